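"""Signal-window tables, hexamer clustering, consensus elements, profiles."""

import numpy as np
import pytest

from polyasig.schema import (REGION_SCHEMAS, align_and_consensus, build_schema,
                             cluster_hexamers, hexamer_distance,
                             nucleotide_profile, segment_regions,
                             select_significant_hexamers, write_pfms)
from polyasig.simulate import SignalSpec, simulate_flank_set
from polyasig.sites import FlankSequence


GOLDEN_WINDOWS = {
    "3UTR": [("USE", -100, -35), ("PE", -34, -13), ("CEL", -12, -3),
             ("CER", 1, 33), ("DSE", 34, 100)],
    "5UTR": [("USE", -100, -40), ("PE", -40, -10), ("CE", -10, 10),
             ("DSE", 10, 100)],
    "CDS": [("USE", -100, -30), ("CE", -30, 30), ("DSE", 30, 100)],
    "intron": [("USE", -100, -40), ("PE", -40, -10), ("CEL", -10, -1),
               ("CER", 1, 30), ("DSE", 30, 100)],
}


@pytest.mark.parametrize("cls", sorted(GOLDEN_WINDOWS))
def test_region_windows_match_published_models(cls):
    assert segment_regions(cls).windows == GOLDEN_WINDOWS[cls]


def test_unknown_class_rejected():
    with pytest.raises(ValueError, match="unknown site class"):
        segment_regions("promoter")


def test_windows_cover_span_without_gaps():
    for cls, windows in REGION_SCHEMAS.items():
        for (_, _, e1), (_, s2, _) in zip(windows, windows[1:]):
            # consecutive windows abut, share a printed boundary, or leave
            # only the cleavage dinucleotide gap between CEL and CER
            assert 0 <= s2 - e1 <= 4


def test_hexamer_distance_cases():
    assert hexamer_distance("AAUAAA", "AAUAAA") == 0.0
    # one-step shift alignment: AAUAAA[1:] == AUAAAA[:5]
    assert hexamer_distance("AAUAAA", "AUAAAA") == 0.5
    assert hexamer_distance("AAUAAA", "GGCGCC") >= 2.6
    assert hexamer_distance("AAUAAA", "AUUAAA") == 1.0  # single mismatch


def test_clustering_groups_and_separates():
    groups = cluster_hexamers(["AAUAAA", "AUAAAA", "GGCGCC"])
    sets = sorted(map(frozenset, groups), key=len)
    assert frozenset(["GGCGCC"]) in sets
    assert frozenset(["AAUAAA", "AUAAAA"]) in sets
    assert cluster_hexamers(["AAUAAA"]) == [["AAUAAA"]]


def test_clustering_membership_permutation_invariant(rng):
    hexamers = ["AAUAAA", "AUUAAA", "AAUAAG", "UUUUUU", "UUUUUA", "GGCGCC"]
    ref = sorted(map(frozenset, cluster_hexamers(hexamers)))
    for _ in range(5):
        perm = [hexamers[i] for i in rng.permutation(len(hexamers))]
        assert sorted(map(frozenset, cluster_hexamers(perm))) == ref


def test_align_single_member_one_hot():
    el = align_and_consensus(["AAUAAA"], region="PE", rank=1)
    assert el.consensus == "AAUAAA" and el.label == "PE.1"
    assert (el.pfm.sum(axis=0) == 1).all()
    assert el.pfm.loc["A", 0] == 1 and el.pfm.loc["U", 2] == 1


def test_align_shifted_group_column_sums():
    el = align_and_consensus(["AAUAAA", "AUAAAA", "AAUAAU"])
    assert 7 <= el.pfm.shape[1] <= 8
    sums = el.pfm.sum(axis=0)
    covered = sums[sums == 3]
    assert len(covered) >= 5  # fully covered columns carry all members


def test_consensus_majority_vote_recovers_seed_motif():
    group = ["AAUAAA", "AAUAAC", "AGUAAA", "AAUGAA", "AAUAUA"]
    el = align_and_consensus(group)
    assert el.consensus == "AAUAAA"


def test_select_significant_hexamers_cutoff_extremes():
    import pandas as pd

    tab = pd.DataFrame({"z_oe": np.linspace(-2, 10, 100)},
                       index=[f"k{i}" for i in range(100)])
    sw = pd.DataFrame({"z_sw": np.full(100, 5.0)}, index=tab.index)
    everything = select_significant_hexamers(tab, None, q=0.999999)
    assert len(everything) >= 99  # threshold below nearly all values
    none = select_significant_hexamers(tab, sw, z_sw_cut=np.inf)
    assert none == []
    top = select_significant_hexamers(tab, None, q=0.01)
    assert top == ["k99"]


def test_nucleotide_profile_sums_and_ya_peak():
    flanks = [FlankSequence(site_id=str(i), up="A" * 50, down="A" * 20)
              for i in range(3)]
    prof = nucleotide_profile(flanks, rel_range=(-50, 20))
    assert np.allclose(prof.sum(axis=1), 1.0)
    assert (prof["A"] == 1.0).all()
    # YA-planted flanks show the Y at -2 and the A peak at -1
    grammar = (SignalSpec("AAUAAA", "3UTR", -23, 4.0, 0.5),)
    planted, _ = simulate_flank_set(400, grammar, seed=2, ya_fraction=1.0)
    prof = nucleotide_profile(planted, rel_range=(-5, 5))
    assert prof.loc[-1, "A"] > 0.9
    assert prof.loc[-2, "C"] + prof.loc[-2, "U"] > 0.9


def test_build_schema_recovers_planted_elements_in_correct_windows():
    grammar = (SignalSpec("AAUAAA", "3UTR", -23, 4.0, 0.6),
               SignalSpec("AUUAAA", "3UTR", -23, 4.0, 0.25),
               SignalSpec("UGUUUU", "3UTR", 20, 4.0, 0.5))
    flanks, _ = simulate_flank_set(500, grammar, seed=6)
    reports = build_schema({"3UTR": flanks})
    table = reports["3UTR"].table
    pe = table[table.window == "PE"]
    assert any("AAUAAA" in t for t in pe.top_hexamers)
    cer = table[table.window == "CER"]
    assert any("UGUUUU" in t for t in cer.top_hexamers)
    # the PE signal family is not reported in DSE
    dse = table[table.window == "DSE"]
    assert not any("AAUAAA" in t for t in dse.top_hexamers)
    # labels rank by member count within each window
    for _, grp in table.groupby("window"):
        ranks = [int(e.split(".")[1]) for e in grp.element]
        assert ranks == sorted(ranks)
        assert list(grp.n_hexamers) == sorted(grp.n_hexamers, reverse=True)


def test_write_pfms_jaspar_roundtrippable(tmp_path):
    el = align_and_consensus(["AAUAAA", "AUUAAA"], region="PE", rank=1)
    path = tmp_path / "el.jaspar"
    write_pfms([el], path)
    text = path.read_text()
    assert text.startswith(">PE.1")
    assert "A [" in text and "U [" in text
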