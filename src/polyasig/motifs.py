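"""Markov-background k-mer statistics for poly(A) signal discovery.

The over-representation machinery works on RNA-alphabet sequences (``ACGU``;
``N`` positions are excluded from counting). A first-order Markov chain fitted
to the scanned region supplies the null model: the expected per-position
probability of a word w is

    f_e(w) = prod_i f_o(w_i w_{i+1}) / prod_interior f_o(w_i)

(the chain probability written in dinucleotide/mononucleotide frequencies).
Expected counts over a sequence set are O_e = f_e * T with T = sum(l_i - k + 1)
scannable start positions, and the z-score z_oe = (O_o - O_e) / SD uses a
standard deviation corrected for word self-overlap: overlapping occurrences of
a periodic word (e.g. AAAAAA) are positively correlated, which inflates the
count variance well past the binomial value. ``kmer_sd`` computes the exact
stationary-chain variance of the occurrence count, including the negative
covariance of incompatible overlaps and the geometric tail coupling through
the chain, so that it matches a Monte-Carlo simulation of the background model
to within sampling error.

Significance is assessed with upper-tail binomial probabilities, positional
dispersion (mean and SD of occurrence positions relative to the cleavage
site), and a greedy masked selection that repeatedly takes the most frequent
still-significant hexamer and removes the sequences it covers. Differential
use between strong and weak sites is a two-proportion z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod, sqrt
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

RNA = "ACGU"
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(RNA):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("T")] = 3  # tolerate DNA input
_CODE[ord("t")] = 3


def encode(seq: str) -> np.ndarray:
    """Map an RNA/DNA string to codes 0..3 (-1 for N/other)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: Iterable[int]) -> str:
    return "".join(RNA[c] for c in codes)


def all_kmers(k: int) -> list[str]:
    out = [""]
    for _ in range(k):
        out = [p + c for p in out for c in RNA]
    return out


# ---------------------------------------------------------------------------
# background model

@dataclass(frozen=True)
class MarkovModel:
    """First-order background: mononucleotide and dinucleotide frequencies."""

    mono: np.ndarray  # shape (4,), sums to 1
    di: np.ndarray    # shape (4,4), sums to 1; di[a,b] = freq of dinucleotide ab
    region: str = ""

    def __post_init__(self):
        if not np.isclose(self.mono.sum(), 1.0, atol=1e-9):
            raise ValueError("mono frequencies must sum to 1")
        if not np.isclose(self.di.sum(), 1.0, atol=1e-9):
            raise ValueError("di frequencies must sum to 1")
        if (self.mono < 0).any() or (self.di < 0).any():
            raise ValueError("frequencies must be non-negative")

    def transition(self) -> np.ndarray:
        """Row-stochastic transition matrix M[a, b] = P(b | a)."""
        rows = self.di.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(rows > 0, self.di / rows, 0.25)
        return M

    @classmethod
    def from_transition(cls, M: np.ndarray, region: str = "") -> "MarkovModel":
        """Build a stationary model from a transition matrix.

        The mononucleotide distribution is the stationary distribution of M,
        so simulated chains are marginally homogeneous — the regime in which
        the variance formula in :func:`kmer_sd` is exact.
        """
        M = np.asarray(M, dtype=float)
        vals, vecs = np.linalg.eig(M.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = pi / pi.sum()
        return cls(mono=pi, di=pi[:, None] * M, region=region)

    def simulate_codes(self, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate n sequences of the given length as an (n, length) code array."""
        M = self.transition()
        cum_m = np.cumsum(self.mono)
        cum_t = np.cumsum(M, axis=1)
        out = np.empty((n, length), dtype=np.int8)
        out[:, 0] = np.searchsorted(cum_m, rng.random(n), side="right")
        for t in range(1, length):
            r = rng.random(n)
            out[:, t] = (cum_t[out[:, t - 1]] < r[:, None]).sum(axis=1)
        return np.minimum(out, 3)


def fit_markov(sequences: Iterable[str], region: str = "") -> MarkovModel:
    """Maximum-likelihood mono/dinucleotide frequencies pooled over sequences.

    Dinucleotides are counted within each sequence only (no wrap-around, no
    joins across sequences); windows touching N are skipped.
    """
    mono = np.zeros(4)
    di = np.zeros((4, 4))
    total = 0
    for seq in sequences:
        codes = encode(seq)
        total += len(codes)
        valid = codes >= 0
        np.add.at(mono, codes[valid], 1)
        a, b = codes[:-1], codes[1:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(di, (a[ok], b[ok]), 1)
    if total < 2:
        raise ValueError("need at least 2 nt of sequence to fit a Markov model")
    if mono.sum() == 0:
        raise ValueError("no countable (non-N) nucleotides in input")
    mono /= mono.sum()
    if di.sum() > 0:
        di /= di.sum()
    else:
        di = np.outer(mono, mono)
    return MarkovModel(mono=mono, di=di, region=region)


def expected_kmer_freq(model: MarkovModel, kmer: str) -> float:
    """Per-position probability of ``kmer`` under the first-order chain.

    Product of the k-1 dinucleotide frequencies divided by the k-2 interior
    mononucleotide frequencies. Returns 0.0 if any required frequency is 0.
    """
    if len(kmer) < 2:
        raise ValueError("kmer must have length >= 2")
    w = encode(kmer)
    if (w < 0).any():
        raise ValueError(f"kmer {kmer!r} contains non-ACGU characters")
    num = prod(model.di[w[i], w[i + 1]] for i in range(len(w) - 1))
    den = prod(model.mono[w[i]] for i in range(1, len(w) - 1))
    if den == 0.0:
        return 0.0
    return num / den


def total_positions(lengths: Iterable[int], k: int) -> int:
    """T = sum over sequences of max(l_i - k + 1, 0) scannable start positions."""
    return sum(max(l - k + 1, 0) for l in lengths)


def expected_occurrences(f_e: float, lengths: Iterable[int], k: int) -> float:
    """O_e = f_e * T. Sequences shorter than k contribute zero positions."""
    return f_e * total_positions(lengths, k)


def word_periods(kmer: str) -> list[int]:
    """Self-overlap periods: d with kmer[i] == kmer[i+d] for all valid i."""
    k = len(kmer)
    return [d for d in range(1, k)
            if all(kmer[i] == kmer[i + d] for i in range(k - d))]


def _tail_table(M: np.ndarray, pi: np.ndarray, t_prime: int) -> np.ndarray:
    """4x4 table of sum_{s=1}^{T'-1} (T'-s) * (M^s[a,b]/pi[b] - 1).

    This is the covariance contribution of occurrence pairs separated by at
    least k (coupled only through the chain's approach to stationarity); it
    vanishes for an iid background and decays geometrically otherwise.
    """
    tail = np.zeros((4, 4))
    Ms = np.eye(4)
    for s in range(1, t_prime):
        Ms = Ms @ M
        tail += (t_prime - s) * (Ms / pi[None, :] - 1.0)
    return tail


def occurrence_variance(model: MarkovModel, kmer: str,
                        lengths: int | Iterable[int],
                        _tail_cache: dict | None = None) -> float:
    """Exact variance of the occurrence count of ``kmer`` under the model.

    ``lengths`` is a single sequence length or an iterable of lengths;
    counts in distinct sequences are independent, so variances add. Assumes
    the chain is marginally stationary (mono = stationary distribution of the
    transition matrix), which holds for fitted models up to edge effects.
    """
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)]
    k = len(kmer)
    fe = expected_kmer_freq(model, kmer)
    if not 0.0 < fe < 1.0:
        raise ValueError(f"degenerate expected frequency f_e={fe} for {kmer!r}")
    M = model.transition()
    pi = model.mono
    w = encode(kmer)
    trans = [M[w[j], w[j + 1]] for j in range(k - 1)]
    periods = set(word_periods(kmer))
    from collections import Counter
    var_total = 0.0
    for length, n_seq in Counter(int(l) for l in lengths).items():
        T = length - k + 1
        if T <= 0:
            continue
        v = T * fe * (1.0 - fe)
        for d in range(1, min(k, T)):
            if d in periods:
                fed = prod(trans[k - 1 - d:])
                cov = fe * (fed - fe)
            else:
                cov = -fe * fe
            v += 2.0 * (T - d) * cov
        t_prime = T - k + 1
        if t_prime >= 2:
            if _tail_cache is not None:
                key = t_prime
                if key not in _tail_cache:
                    _tail_cache[key] = _tail_table(M, pi, t_prime)
                tail = _tail_cache[key]
            else:
                tail = _tail_table(M, pi, t_prime)
            v += 2.0 * fe * fe * tail[w[-1], w[0]]
        var_total += n_seq * v
    return var_total


def kmer_sd(model: MarkovModel, kmer: str, lengths: int | Iterable[int]) -> float:
    """Overlap-corrected standard deviation of the occurrence count."""
    return sqrt(occurrence_variance(model, kmer, lengths))


def z_oe(o_observed: float, o_expected: float, sd: float) -> float:
    if sd <= 0:
        raise ValueError("z_oe undefined for SD <= 0")
    return (o_observed - o_expected) / sd


def binom_pvalue(o_observed: int, n_positions: int, f_e: float,
                 log: bool = False) -> float:
    """Upper-tail cumulative binomial probability P(X >= O_o), X~Bin(T, f_e)."""
    if not 0.0 <= f_e <= 1.0:
        raise ValueError(f"f_e={f_e} outside [0, 1]")
    if not 0 <= o_observed <= n_positions:
        raise ValueError("require 0 <= O_o <= T")
    if o_observed == 0:
        return 0.0 if log else 1.0
    if log:
        return float(stats.binom.logsf(o_observed - 1, n_positions, f_e))
    return float(stats.binom.sf(o_observed - 1, n_positions, f_e))


# ---------------------------------------------------------------------------
# counting

def count_kmers(sequences: Iterable[str], k: int) -> tuple[np.ndarray, int]:
    """Count all 4^k words (overlapping starts) over a sequence set.

    Returns (counts indexed by base-4 word code, total valid positions T).
    Windows containing N are excluded from both counts and T.
    """
    counts = np.zeros(4 ** k, dtype=np.int64)
    T = 0
    weights = 4 ** np.arange(k - 1, -1, -1)
    for seq in sequences:
        codes = encode(seq)
        if len(codes) < k:
            continue
        n_win = len(codes) - k + 1
        idx = np.zeros(n_win, dtype=np.int64)
        valid = np.ones(n_win, dtype=bool)
        for j in range(k):
            c = codes[j:j + n_win]
            valid &= c >= 0
            idx += np.where(c >= 0, c, 0) * weights[j]
        np.add.at(counts, idx[valid], 1)
        T += int(valid.sum())
    return counts, T


def count_word(sequences: Iterable[str], word: str) -> int:
    """Occurrences of one word over a sequence set (overlapping starts)."""
    w = encode(word)
    k = len(w)
    total = 0
    for seq in sequences:
        codes = encode(seq)
        if len(codes) < k:
            continue
        n_win = len(codes) - k + 1
        match = np.ones(n_win, dtype=bool)
        for j in range(k):
            match &= codes[j:j + n_win] == w[j]
        total += int(match.sum())
    return total


def count_word_in_codes(codes: np.ndarray, word: str) -> np.ndarray:
    """Per-row occurrence counts of ``word`` in an (n, L) code matrix."""
    w = encode(word)
    k = len(w)
    n_win = codes.shape[1] - k + 1
    match = np.ones((codes.shape[0], n_win), dtype=bool)
    for j in range(k):
        match &= codes[:, j:j + n_win] == w[j]
    return match.sum(axis=1)


def kmer_stat_table(sequences: Sequence[str], k: int = 6,
                    model: MarkovModel | None = None):
    """Per-kmer observed/expected/SD/z/p table for one region's sequences.

    Returns a pandas DataFrame indexed by kmer with columns
    ``o_observed, f_e, o_expected, sd, z_oe, p_binom``.
    """
    import pandas as pd

    if model is None:
        model = fit_markov(sequences)
    counts, T = count_kmers(sequences, k)
    lengths = [len(s) for s in sequences]
    tail_cache: dict = {}
    rows = []
    for code, kmer in enumerate(all_kmers(k)):
        o_o = int(counts[code])
        fe = expected_kmer_freq(model, kmer)
        o_e = expected_occurrences(fe, lengths, k)
        if 0.0 < fe < 1.0:
            sd = sqrt(occurrence_variance(model, kmer, lengths, tail_cache))
            z = z_oe(o_o, o_e, sd)
            p = binom_pvalue(o_o, T, fe)
        else:
            sd, z, p = float("nan"), float("nan"), 1.0
        rows.append((kmer, o_o, fe, o_e, sd, z, p))
    df = pd.DataFrame(rows, columns=["kmer", "o_observed", "f_e", "o_expected",
                                     "sd", "z_oe", "p_binom"]).set_index("kmer")
    df.attrs["total_positions"] = T
    return df


# ---------------------------------------------------------------------------
# positional statistics and greedy selection

def occurrence_positions(flank, kmer: str) -> list[int]:
    """Relative coordinates (of the 3'-most base) of every occurrence in a flank.

    The position convention matches planted-motif offsets: a hexamer reported
    at -23 occupies relative -28..-23.
    """
    seq = flank.seq
    codes = encode(seq)
    w = encode(kmer)
    k = len(w)
    if len(codes) < k:
        return []
    n_win = len(codes) - k + 1
    match = np.ones(n_win, dtype=bool)
    for j in range(k):
        match &= codes[j:j + n_win] == w[j]
    starts = np.nonzero(match)[0]
    return [flank.rel_of(int(s) + k - 1) for s in starts]


def positional_stats(flanks, kmer: str,
                     window: tuple[int, int]) -> tuple[float, float]:
    """Mean and population SD of occurrence positions within a relative window.

    Occurrence position is the relative coordinate of the word's 3'-most
    base. Raises if no occurrence falls in the window.
    """
    a, b = window
    if a > b:
        raise ValueError("window start must be <= end")
    flanks = list(flanks)
    if not flanks:
        raise ValueError("no flanks given")
    max_up = max(len(f.up) for f in flanks)
    max_down = max(len(f.down) for f in flanks)
    if a < -max_up or b > max(max_down, -1 if b < 0 else 0):
        raise ValueError("window outside flank bounds")
    positions = []
    for f in flanks:
        positions.extend(p for p in occurrence_positions(f, kmer) if a <= p <= b)
    if not positions:
        raise ValueError(f"no occurrence of {kmer!r} in window {window}")
    arr = np.asarray(positions, dtype=float)
    return float(arr.mean()), float(arr.std())


@dataclass
class SignalHit:
    """One hexamer accepted by the greedy selection."""

    kmer: str
    round: int
    o_observed: int          # count in the current set at selection time
    o_expected: float
    total_positions: int
    p_value: float
    mean_pos: float          # positional stats on the original set
    pos_sd: float
    coverage: float          # fraction of original flanks with >=1 hit in window


def greedy_signal_selection(flanks, window: tuple[int, int], k: int = 6,
                            p_cut: float = 1e-5, sd_cut: float = 7.0,
                            sd_margin: int = 15,
                            sd_window: tuple[int, int] | None = None,
                            model: MarkovModel | None = None,
                            mode: str = "remove",
                            max_rounds: int = 100) -> list[SignalHit]:
    """Iteratively select significant, positionally concentrated k-mers.

    Each round counts all k-mers in the current sequence set restricted to
    ``window``, walks candidates in descending frequency (ties broken
    lexicographically), and accepts the first whose upper-tail binomial
    probability against the background model is below ``p_cut`` and whose
    positional SD — always measured on the ORIGINAL flank set, over
    ``sd_window`` (default: the selection window widened by ``sd_margin`` nt
    per side) — is at most ``sd_cut``. Accepted k-mers remove every sequence
    containing them in the window (``mode="remove"``) or mask just the covered
    positions with N (``mode="mask"``). Terminates when no candidate passes.

    The dispersion window is wider than the counting window so that words
    scattered across the whole flank are penalized, while a word concentrated
    at its planted offset keeps a small SD even counting the few background
    occurrences admitted by the margin.
    """
    if window[0] > window[1]:
        raise ValueError("empty selection window")
    if mode not in ("remove", "mask"):
        raise ValueError(f"unknown mode {mode!r}")
    flanks = list(flanks)
    if not flanks:
        return []
    if sd_window is None:
        max_up = max(len(f.up) for f in flanks)
        max_down = max(len(f.down) for f in flanks)
        lo = max(window[0] - sd_margin, -max_up)
        hi = min(window[1] + sd_margin, max_down if max_down > 0 else -1)
        if lo == 0:
            lo = 1
        if hi == 0:
            hi = -1
        sd_window = (lo, hi)
    original = [f.window(*window) for f in flanks]
    seqs = list(original)
    if model is None:
        model = fit_markov([s for s in seqs if len(s) >= 2])
    kmers = np.asarray(all_kmers(k))
    pos_cache: dict[str, tuple[float, float] | None] = {}
    rejected_sd: set[str] = set()
    hits: list[SignalHit] = []

    def pos_stats(kmer: str):
        if kmer not in pos_cache:
            try:
                pos_cache[kmer] = positional_stats(flanks, kmer, sd_window)
            except ValueError:
                pos_cache[kmer] = None
        return pos_cache[kmer]

    for rnd in range(1, max_rounds + 1):
        live = [s for s in seqs if len(s) >= k]
        if not live:
            break
        counts, T = count_kmers(live, k)
        order = np.lexsort((kmers, -counts))
        selected = None
        for code in order:
            o_o = int(counts[code])
            if o_o == 0:
                break
            kmer = str(kmers[code])
            if kmer in rejected_sd:
                continue
            fe = expected_kmer_freq(model, kmer)
            if not 0.0 < fe < 1.0:
                continue
            p = binom_pvalue(o_o, T, fe)
            if p >= p_cut:
                continue
            ps = pos_stats(kmer)
            if ps is None or ps[1] > sd_cut:
                rejected_sd.add(kmer)
                continue
            cov = sum(count_word([s], kmer) > 0 for s in original) / len(original)
            selected = SignalHit(kmer=kmer, round=rnd, o_observed=o_o,
                                 o_expected=fe * T, total_positions=T,
                                 p_value=p, mean_pos=ps[0], pos_sd=ps[1],
                                 coverage=cov)
            break
        if selected is None:
            break
        hits.append(selected)
        if mode == "remove":
            seqs = [s for s in seqs if count_word([s], selected.kmer) == 0]
        else:
            seqs = [_mask_word(s, selected.kmer) for s in seqs]
    return hits


def _mask_word(seq: str, word: str) -> str:
    k = len(word)
    out = list(seq)
    start = seq.find(word)
    while start != -1:
        out[start:start + k] = "N" * k
        start = seq.find(word, start + 1)
    return "".join(out)


# ---------------------------------------------------------------------------
# strong vs weak differential statistic

def z_sw(o_s: int, o_w: int, n_s: int, n_w: int,
         printed_form: bool = False) -> tuple[float, float]:
    """Two-proportion z for a k-mer's occurrence in strong vs weak site sets.

    Returns (pooled probability p, z). With ``printed_form=True`` the
    numerator uses raw counts rather than proportions (the form some older
    reports print); the default is the standard two-proportion statistic.
    """
    if n_s <= 0 or n_w <= 0:
        raise ValueError("N_s and N_w must be positive")
    p = (o_s + o_w) / (n_s + n_w)
    if p <= 0.0 or p >= 1.0:
        raise ValueError(f"pooled probability p={p} degenerate; z undefined")
    denom = sqrt(p * (1.0 - p) * (1.0 / n_s + 1.0 / n_w))
    if printed_form:
        z = (o_s - o_w) / denom
    else:
        z = (o_s / n_s - o_w / n_w) / denom
    return p, z


def strong_weak_table(strong_seqs: Sequence[str], weak_seqs: Sequence[str],
                      k: int = 6):
    """Per-kmer two-proportion statistics between strong and weak site sets."""
    import pandas as pd

    cs, ns = count_kmers(strong_seqs, k)
    cw, nw = count_kmers(weak_seqs, k)
    rows = []
    for code, kmer in enumerate(all_kmers(k)):
        o_s, o_w = int(cs[code]), int(cw[code])
        try:
            p, z = z_sw(o_s, o_w, ns, nw)
            pval = 2.0 * stats.norm.sf(abs(z))
        except ValueError:
            p, z, pval = float("nan"), float("nan"), float("nan")
        rows.append((kmer, o_s, o_w, ns, nw, p, z, pval))
    return pd.DataFrame(rows, columns=["kmer", "o_strong", "o_weak", "n_strong",
                                       "n_weak", "pooled_p", "z_sw", "p_value"]
                        ).set_index("kmer")
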