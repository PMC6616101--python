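"""Clustering, internal-priming filters and flank extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyasig._util import revcomp
from polyasig.io import Genome
from polyasig.sites import (CleavageEvent, FlankSequence, PolyACluster,
                            classify_window, cluster_cleavage_events,
                            extract_flank, filter_a_rich)


def _ev(pos, total=1, chrom="chr1", strand="+"):
    return CleavageEvent(chrom=chrom, strand=strand, position=pos,
                         counts=np.array([total]), event_id=f"e{pos}")


def _brute_force_chains(positions, max_gap):
    """Oracle: all-pairs chaining by transitive closure."""
    positions = sorted(positions)
    chains = [[positions[0]]]
    for p in positions[1:]:
        if p - chains[-1][-1] <= max_gap:
            chains[-1].append(p)
        else:
            chains.append([p])
    return [tuple(c) for c in chains]


def test_gap_boundary_splits_and_chains():
    clusters = cluster_cleavage_events([_ev(100), _ev(110), _ev(140)])
    assert sorted(tuple(e.position for e in c.members) for c in clusters) \
        == [(100, 110), (140,)]
    # chained: consecutive gaps 20 and 24 are both <= 24
    clusters = cluster_cleavage_events([_ev(100), _ev(120), _ev(144)])
    assert len(clusters) == 1


def test_singleton_cluster_represents_itself():
    (c,) = cluster_cleavage_events([_ev(500, total=3)])
    assert c.representative == 500 and c.total == 3


@settings(deadline=None, derandomize=True)
@given(st.sets(st.integers(min_value=1, max_value=2000), min_size=1,
               max_size=40),
       st.integers(min_value=0, max_value=50))
def test_clustering_matches_brute_force_and_input_order(positions, max_gap):
    events = [_ev(p) for p in positions]
    expected = _brute_force_chains(positions, max_gap)
    for perm_seed in (0, 1):
        rng = np.random.default_rng(perm_seed)
        shuffled = [events[i] for i in rng.permutation(len(events))]
        clusters = cluster_cleavage_events(shuffled, max_gap=max_gap)
        got = sorted(tuple(e.position for e in c.members) for c in clusters)
        assert got == sorted(expected)


def test_representative_is_max_count_tie_most_downstream():
    clusters = cluster_cleavage_events([_ev(100, 5), _ev(110, 5), _ev(105, 2)])
    assert clusters[0].representative == 110  # tie broken downstream (+)
    clusters = cluster_cleavage_events(
        [_ev(100, 5, strand="-"), _ev(110, 5, strand="-")])
    assert clusters[0].representative == 100  # downstream on minus strand


def test_duplicate_events_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        cluster_cleavage_events([_ev(5), _ev(5)])


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        CleavageEvent(chrom="c", strand="+", position=1,
                      counts=np.array([-1, 2]))


@pytest.mark.parametrize("window,status", [
    ("AAAAAACGTA", "fail_ARS"),        # six adenines in 10 nt
    ("AGAACCCCCC", "fail_tetramer"),   # AGAA immediately downstream
    ("ACGTACGTAC", "pass"),
    ("AAGAGGGGGG", "fail_tetramer"),
    ("CAGTAAAAAG", "fail_ARS"),        # 6 A total, run of 5 only
    ("CCCCAAAAAC", "pass"),            # 5 A: below every rule
])
def test_a_rich_window_rules(window, status):
    assert classify_window(window) == status


def test_filter_uses_sense_strand_window():
    # minus-strand site at 20: downstream is 10..19 on the minus sense,
    # i.e. revcomp(genome[10:19]) must be A-rich to fail
    seq = "G" * 9 + "T" * 10 + "G" * 21
    genome = Genome({"chr1": seq})
    c = PolyACluster(chrom="chr1", strand="-", members=[], representative=20,
                     counts=np.array([1]))
    assert filter_a_rich(c, genome) == "fail_ARS"


def test_contig_edge_kept_and_flagged():
    genome = Genome({"chr1": "A" * 25})
    c = PolyACluster(chrom="chr1", strand="+", members=[], representative=20,
                     counts=np.array([1]))
    assert filter_a_rich(c, genome) == "pass"
    assert c.edge_flag


def test_extract_flank_plus_strand_coordinates():
    seq = "".join("ACGT"[i % 4] for i in range(1000))
    genome = Genome({"chr1": seq})
    c = PolyACluster(chrom="chr1", strand="+", members=[], representative=500,
                     counts=np.array([1]), cluster_id="s1")
    f = extract_flank(c, genome)
    # relative -1 is the site nucleotide itself; +1 the next one
    assert f.up == seq[200:500].replace("T", "U")
    assert f.down == seq[500:600].replace("T", "U")
    assert not f.up_truncated and not f.down_truncated


def test_extract_flank_strand_symmetry():
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
    plus = Genome({"chr1": seq})
    minus = Genome({"chr1": revcomp(seq)})
    p = 400
    cp = PolyACluster(chrom="chr1", strand="+", members=[], representative=p,
                      counts=np.array([1]))
    cm = PolyACluster(chrom="chr1", strand="-", members=[],
                      representative=len(seq) - p + 1, counts=np.array([1]))
    fp = extract_flank(cp, plus)
    fm = extract_flank(cm, minus)
    assert fp.up == fm.up and fp.down == fm.down


def test_extract_flank_truncates_at_contig_edge():
    genome = Genome({"chr1": "A" * 150})
    c = PolyACluster(chrom="chr1", strand="+", members=[], representative=100,
                     counts=np.array([1]))
    f = extract_flank(c, genome)
    assert len(f.up) == 100 and f.up_truncated
    assert len(f.down) == 50 and f.down_truncated


def test_extract_flank_missing_chromosome_named():
    genome = Genome({"chr1": "ACGT" * 100})
    c = PolyACluster(chrom="chrX", strand="+", members=[], representative=50,
                     counts=np.array([1]))
    with pytest.raises(KeyError, match="chrX"):
        extract_flank(c, genome)


def test_flank_window_coordinates():
    f = FlankSequence(site_id="x", up="ACGUA", down="GGCC")
    assert f.window(-5, -1) == "ACGUA"
    assert f.window(1, 4) == "GGCC"
    assert f.window(-2, 2) == "UAGG"
    assert f.rel_of(f.idx_of(-3)) == -3
    assert f.rel_of(f.idx_of(2)) == 2


def test_filter_closed_loop_on_synthetic_data(sim_result, sim_clusters):
    genome = sim_result.genome
    removed = {c.cluster_id for c in sim_clusters
               if filter_a_rich(c, genome) != "pass"}
    flagged = set(sim_result.truth.site_id[sim_result.truth.artifact])
    assert removed == flagged


def test_cluster_counts_sum_members(sim_result, sim_clusters):
    counts = sim_result.counts
    for c in sim_clusters[:50]:
        member_ids = [e.event_id for e in c.members]
        assert (c.counts == counts.loc[member_ids].sum(axis=0).to_numpy()).all()
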