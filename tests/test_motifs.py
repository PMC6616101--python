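"""Markov background, overlap-corrected variance, positional statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyasig.motifs import (MarkovModel, all_kmers, binom_pvalue, count_kmers,
                             count_word, expected_kmer_freq,
                             expected_occurrences, fit_markov,
                             greedy_signal_selection, kmer_sd,
                             positional_stats, total_positions, word_periods,
                             z_oe, z_sw)
from polyasig.simulate import SignalSpec, simulate_flank_set
from polyasig.sites import FlankSequence


def chain_probability(pi, M, word_codes):
    """Independent oracle: walk the chain explicitly."""
    p = pi[word_codes[0]]
    for a, b in zip(word_codes, word_codes[1:]):
        p *= M[a, b]
    return p


def test_fit_markov_degenerate_and_two_letter_cases():
    m = fit_markov(["AAAA"])
    assert m.mono[0] == 1.0 and m.di[0, 0] == 1.0
    m = fit_markov(["AU"])
    assert m.mono[0] == 0.5 and m.mono[3] == 0.5 and m.di[0, 3] == 1.0
    with pytest.raises(ValueError):
        fit_markov([])


def test_fit_markov_recovers_uniform_composition(rng):
    seqs = ["".join("ACGU"[i] for i in rng.integers(0, 4, 100))
            for _ in range(5000)]
    m = fit_markov(seqs)
    assert np.allclose(m.mono, 0.25, atol=0.01)


def test_expected_freq_uniform_reduces_to_iid_product():
    m = MarkovModel(mono=np.full(4, 0.25), di=np.full((4, 4), 0.0625))
    assert expected_kmer_freq(m, "AAUAAA") == pytest.approx(0.25 ** 6,
                                                            rel=1e-12)


def test_expected_freq_matches_chain_enumeration_oracle(rng):
    # small version of the full acceptance sweep: random models, all hexamers
    for _ in range(3):
        M = rng.dirichlet(np.ones(4) * 2, size=4)
        model = MarkovModel.from_transition(M)
        pi = model.mono
        for codes in itertools.product(range(4), repeat=4):
            kmer = "".join("ACGU"[c] for c in codes)
            assert expected_kmer_freq(model, kmer) == pytest.approx(
                chain_probability(pi, M, codes), abs=1e-14)


def test_expected_occurrences_arithmetic():
    assert expected_occurrences(0.001, [105] * 100, 6) == pytest.approx(10.0)
    assert expected_occurrences(0.0, [100], 6) == 0.0
    assert total_positions([10, 6, 5], 6) == 6  # 5 + 1 + 0


def test_word_periods():
    assert word_periods("AAUGGC") == []
    assert word_periods("AAAAAA") == [1, 2, 3, 4, 5]
    assert word_periods("UGUGUG") == [2, 4]
    # AAUAAA self-overlaps at shifts 4 (..AA) and 5 (..A)
    assert word_periods("AAUAAA") == [4, 5]


def test_overlapping_word_sd_exceeds_naive_binomial():
    Ma = np.array([[0.55, 0.15, 0.15, 0.15],
                   [0.40, 0.20, 0.20, 0.20],
                   [0.40, 0.20, 0.20, 0.20],
                   [0.35, 0.15, 0.15, 0.35]])
    model = MarkovModel.from_transition(Ma)
    fe = expected_kmer_freq(model, "AAAAAA")
    naive = math.sqrt(95 * fe * (1 - fe))
    assert kmer_sd(model, "AAAAAA", 100) > naive * 1.3


def test_kmer_sd_matches_monte_carlo(rng):
    # small in-suite check; the acceptance test runs the full-size oracle
    from polyasig.motifs import count_word_in_codes

    model = MarkovModel.from_transition(np.full((4, 4), 0.25))
    codes = model.simulate_codes(4000, 100, rng)
    for word in ("AAUAAA", "AAAAAA"):
        counts = count_word_in_codes(codes, word)
        emp = counts.std(ddof=1)
        m2 = counts.var(ddof=1)
        m4 = ((counts - counts.mean()) ** 4).mean()
        se = math.sqrt(max(m4 - m2 ** 2, 0.0) / (4 * m2 * len(counts)))
        assert kmer_sd(model, word, 100) == pytest.approx(emp, abs=3 * se)


def test_kmer_sd_degenerate_frequency_rejected():
    m = MarkovModel(mono=np.array([1.0, 0, 0, 0]),
                    di=np.array([[1.0, 0, 0, 0], [0] * 4, [0] * 4, [0] * 4]))
    assert expected_kmer_freq(m, "AAAAAA") == 1.0
    with pytest.raises(ValueError, match="degenerate"):
        kmer_sd(m, "AAAAAA", 100)
    with pytest.raises(ValueError, match="degenerate"):
        kmer_sd(m, "CCCCCC", 100)


def test_z_oe_identities():
    assert z_oe(10.0, 10.0, 2.0) == 0.0
    assert z_oe(14.0, 10.0, 2.0) == 2.0
    with pytest.raises(ValueError):
        z_oe(1.0, 1.0, 0.0)


def test_binom_pvalue_reference_values():
    assert binom_pvalue(0, 10, 0.1) == 1.0
    expected = 1.0 - 0.9 ** 10 - 10 * 0.1 * 0.9 ** 9
    assert binom_pvalue(2, 10, 0.1) == pytest.approx(expected, rel=1e-12)
    assert binom_pvalue(100, 100, 0.5) == pytest.approx(2.0 ** -100, rel=1e-9)
    assert binom_pvalue(100, 100, 0.5, log=True) == pytest.approx(
        -100 * math.log(2), rel=1e-9)
    with pytest.raises(ValueError):
        binom_pvalue(2, 10, 1.5)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.text(alphabet="ACGUN", min_size=0, max_size=30),
                min_size=1, max_size=8),
       st.integers(min_value=1, max_value=4))
def test_kmer_counts_partition_total_positions(seqs, k):
    counts, T = count_kmers(seqs, k)
    assert counts.sum() == T
    clean = [s for s in seqs if "N" not in s]
    if clean and all("N" not in s for s in seqs):
        assert T == total_positions([len(s) for s in seqs], k)


def _flank_with(up_motifs, up=60, down=20):
    """Build a flank of C's with AAUAAA written at given end-offsets."""
    seq = ["C"] * (up + down)
    for off in up_motifs:
        idx = off + up  # relative<0 -> index off+up
        seq[idx - 5:idx + 1] = list("AAUAAA")
    return FlankSequence(site_id="t", up="".join(seq[:up]),
                         down="".join(seq[up:]))


def test_positional_stats_mean_and_sd():
    f1 = _flank_with([-23])
    assert positional_stats([f1, f1], "AAUAAA", (-40, -1)) == (-23.0, 0.0)
    f2 = _flank_with([-21])
    f3 = _flank_with([-25])
    mean, sd = positional_stats([f2, f3], "AAUAAA", (-40, -1))
    assert mean == -23.0 and sd == 2.0
    with pytest.raises(ValueError, match="no occurrence"):
        positional_stats([f1], "GGGGGG", (-40, -1))
    with pytest.raises(ValueError, match="outside"):
        positional_stats([f1], "AAUAAA", (-500, -1))


def test_z_sw_reference_values():
    p, z = z_sw(30, 10, 1000, 1000)
    assert p == pytest.approx(0.02)
    assert z == pytest.approx((0.03 - 0.01) / math.sqrt(0.02 * 0.98 * 0.002),
                              rel=1e-9)
    assert z == pytest.approx(3.194, abs=5e-3)
    _, z0 = z_sw(20, 20, 1000, 1000)
    assert z0 == 0.0
    # printed (count-numerator) form recoverable for archaeology
    _, zp = z_sw(30, 10, 1000, 1000, printed_form=True)
    assert zp == pytest.approx(z * 1000, rel=1e-9)
    with pytest.raises(ValueError):
        z_sw(0, 0, 1000, 1000)


def test_greedy_selects_only_planted_signal():
    grammar = (SignalSpec("AAUAAA", "3UTR", -23, 3.0, 1.0),)
    flanks, _ = simulate_flank_set(300, grammar, seed=9)
    hits = greedy_signal_selection(flanks, (-34, -13))
    assert hits and hits[0].kmer == "AAUAAA"
    assert hits[0].coverage > 0.9


def test_greedy_rejects_scattered_decoy_keeps_concentrated_signal():
    grammar = (SignalSpec("AAUAAA", "3UTR", -23, 4.0, 0.6),
               SignalSpec("CGCGCG", "3UTR", 0, 0, 0.9,
                          uniform_range=(-100, 100)))
    flanks, _ = simulate_flank_set(600, grammar, seed=10)
    hits = greedy_signal_selection(flanks, (-34, -13))
    kmers = [h.kmer for h in hits]
    assert kmers[0] == "AAUAAA"
    assert "CGCGCG" not in kmers
    assert abs(hits[0].mean_pos + 23) < 1.0 and hits[0].pos_sd <= 7.0


def test_greedy_mask_mode_recovers_signal_and_terminates():
    grammar = (SignalSpec("AAUAAA", "3UTR", -23, 3.0, 1.0),)
    flanks, _ = simulate_flank_set(300, grammar, seed=14)
    hits = greedy_signal_selection(flanks, (-34, -13), mode="mask")
    assert hits and hits[0].kmer == "AAUAAA"


def test_count_word_overlapping_occurrences():
    assert count_word(["AAAA"], "AA") == 3
    assert count_word(["AAUAAUAA"], "AAU") == 2
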