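"""Null models for motif enrichment and depletion.

Two nulls are implemented:

* a composition-preserving **shuffle null** — each sequence is permuted
  uniformly at random, the motif count is re-measured in R replicate
  shuffled proteomes, and the fold change is the observed count divided by
  the mean replicate count;
* a zero-order **Markov null (M0)** for the overlapping diproline word
  "PP" — the expected count and variance follow in closed form from the
  amino-acid composition, and p-values come either from an exact
  dynamic-programming count distribution (short inputs) or from a Gaussian
  approximation with continuity correction.

Fold change = N_obs / N_exp; values below 1 indicate depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import count_pp_runs

_P = ord("P")


@dataclass
class FoldChangeResult:
    """Observed count vs a null expectation.

    ``expected`` holds the R replicate counts for the shuffle null, or is
    None for the analytic Markov null (where ``variance`` is set instead).
    ``fold_change`` is NaN and ``degenerate`` True when n_exp == 0.
    """

    n_obs: int
    n_exp: float
    fold_change: float
    p_value: float
    null_kind: str  # "SHUFFLE" | "MARKOV_M0"
    alternative: str  # "depletion" | "enrichment" | "two-sided"
    expected: np.ndarray | None = None
    variance: float | None = None
    degenerate: bool = False
    branch: str | None = None  # exact / gaussian, Markov null only


@dataclass
class MarkovNull:
    """Zero-order Markov model: i.i.d. letters with the given frequencies."""

    letter_freqs: dict[str, float]
    source: str = ""
    order: int = 0

    def __post_init__(self):
        total = float(sum(self.letter_freqs.values()))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"letter frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.letter_freqs.values()):
            raise ValueError("negative letter frequency")
        if self.order != 0:
            raise NotImplementedError("only Markov order 0 is supported")

    @property
    def f_p(self) -> float:
        return float(self.letter_freqs.get("P", 0.0))

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], source: str = "") -> "MarkovNull":
        counts: dict[str, int] = {}
        for seq in sequences:
            for ch in seq:
                counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no letters to estimate frequencies from")
        return cls({k: v / total for k, v in sorted(counts.items())}, source=source)


# ---------------------------------------------------------------------------
# Shuffle null


def _rng_for(seed: int, replicate: int, seq_index: int) -> np.random.Generator:
    # Counter-based stream splitting: one independent stream per
    # (replicate, sequence) pair, reproducible from the root seed alone.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate, seq_index)))


def shuffle_sequence(sequence: str, seed: int, replicate: int = 0, seq_index: int = 0) -> str:
    """Uniform random permutation of the letters (composition preserved)."""
    if not sequence:
        raise ValueError("empty sequence")
    rng = _rng_for(seed, replicate, seq_index)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")


def default_pp_counter(sequence: str) -> int:
    """Count maximal runs of >=2 prolines (the motif count, strength-blind)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return count_pp_runs(arr == _P)


def count_pp_words(sequence: str) -> int:
    """Count overlapping occurrences of the word "PP" (SPatt semantics).

    A run of k prolines contributes k-1 occurrences.  This is the counter
    paired with the Markov M0 expectation, which is also defined on
    overlapping word occurrences; using it on both sides keeps the fold
    change centred on 1 under the null.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_p = arr == _P
    if is_p.size < 2:
        return 0
    return int(np.count_nonzero(is_p[:-1] & is_p[1:]))


def shuffle_replicate_counts(
    sequences: Sequence[str],
    replicates: int,
    seed: int,
    motif_counter: Callable[[str], int] | None = None,
) -> np.ndarray:
    """Total motif count in each of R shuffled copies of the sequence set.

    Counts are summed over all sequences within a replicate before any
    ratio is formed.  When ``motif_counter`` is None a vectorised run
    counter over the permuted proline mask is used (the count of maximal
    P-runs depends only on where the prolines land).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    totals = np.zeros(replicates, dtype=np.int64)
    arrays = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in sequences]
    for i, arr in enumerate(arrays):
        if motif_counter is None and not np.any(arr == _P):
            continue  # no prolines: zero in every replicate
        for r in range(replicates):
            rng = _rng_for(seed, r, i)
            perm = rng.permutation(arr)
            if motif_counter is None:
                totals[r] += count_pp_runs(perm == _P)
            else:
                totals[r] += motif_counter(perm.tobytes().decode("ascii"))
    return totals


def empirical_p(replicate_counts: np.ndarray, n_obs: int, alternative: str) -> float:
    """Empirical tail probability with the (1+k)/(R+1) pseudocount."""
    r = len(replicate_counts)
    if alternative == "depletion":
        k = int(np.count_nonzero(replicate_counts <= n_obs))
    elif alternative == "enrichment":
        k = int(np.count_nonzero(replicate_counts >= n_obs))
    elif alternative == "two-sided":
        lo = (1 + np.count_nonzero(replicate_counts <= n_obs)) / (r + 1)
        hi = (1 + np.count_nonzero(replicate_counts >= n_obs)) / (r + 1)
        return float(min(1.0, 2 * min(lo, hi)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (r + 1)


def shuffle_fold_change(
    sequences: Sequence[str],
    motif_counter: Callable[[str], int] | None = None,
    replicates: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> FoldChangeResult:
    """Fold change of the aggregate motif count against the shuffle null."""
    counter = motif_counter or default_pp_counter
    n_obs = int(sum(counter(s) for s in sequences))
    counts = shuffle_replicate_counts(sequences, replicates, seed, motif_counter)
    n_exp = float(counts.mean())
    if n_exp == 0.0:
        return FoldChangeResult(
            n_obs=n_obs, n_exp=0.0, fold_change=float("nan"), p_value=float("nan"),
            null_kind="SHUFFLE", alternative=alternative, expected=counts, degenerate=True,
        )
    return FoldChangeResult(
        n_obs=n_obs,
        n_exp=n_exp,
        fold_change=n_obs / n_exp,
        p_value=empirical_p(counts, n_obs, alternative),
        null_kind="SHUFFLE",
        alternative=alternative,
        expected=counts,
    )


def fold_change_vector(
    sequences: Sequence[str],
    motif_counter: Callable[[str], int] | None = None,
    replicates: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Vector of R observed/expected ratios, one per shuffled replicate set.

    The ratio in replicate r is N_obs divided by the aggregate count in the
    r-th shuffled proteome; replicates with zero count are returned as NaN.
    """
    counter = motif_counter or default_pp_counter
    n_obs = sum(counter(s) for s in sequences)
    counts = shuffle_replicate_counts(sequences, replicates, seed, motif_counter).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(counts > 0, n_obs / counts, np.nan)
    return ratios


def per_sequence_fold_changes(
    sequences: Sequence[str],
    motif_counter: Callable[[str], int] | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-sequence fold change: observed count / mean count over R shuffles.

    Sequences whose mean shuffled count is zero (too short, or no prolines)
    are returned as NaN.  Unlike the aggregate ratio vector, these values
    are i.i.d. across sequences drawn from one population, so rank-sum
    comparisons between two populations of sequences are calibrated.
    """
    counter = motif_counter or default_pp_counter
    out = np.full(len(sequences), np.nan)
    for i, seq in enumerate(sequences):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if motif_counter is None and np.count_nonzero(arr == _P) < 2:
            continue
        total = 0
        for r in range(replicates):
            rng = _rng_for(seed, r, i)
            perm = rng.permutation(arr)
            if motif_counter is None:
                total += count_pp_runs(perm == _P)
            else:
                total += motif_counter(perm.tobytes().decode("ascii"))
        if total > 0:
            out[i] = counter(seq) * replicates / total
    return out


# ---------------------------------------------------------------------------
# Markov M0 null for the overlapping word "PP"


def markov_expected_count(
    lengths: Sequence[int], null: MarkovNull, word: str = "PP"
) -> tuple[float, float]:
    """Expectation and variance of the total overlapping "PP" count.

    For one i.i.d. sequence of length L with proline frequency p the count
    N = sum of indicators over the L-1 adjacent pairs, so E[N] = (L-1) p^2.
    Adjacent indicator pairs share a letter: Cov = p^3 - p^4, giving
    Var = (L-1)(p^2 - p^4) + 2(L-2)(p^3 - p^4).  Totals sum over sequences
    (independent sequences).
    """
    if set(word) != {"P"} or len(word) != 2:
        raise NotImplementedError(f"only the homopolymer word 'PP' is supported, got {word!r}")
    p = null.f_p
    exp_total = 0.0
    var_total = 0.0
    for length in lengths:
        if length < len(word):
            raise ValueError(f"sequence length {length} shorter than word")
        m = length - 1
        exp_total += m * p**2
        var_total += m * (p**2 - p**4) + 2 * max(m - 1, 0) * (p**3 - p**4)
    return exp_total, var_total


def pp_count_distribution(length: int, f_p: float) -> np.ndarray:
    """Exact PMF of the overlapping "PP" count in one i.i.d. sequence.

    Dynamic programme over (position, previous-letter-is-P, count); O(L^2).
    """
    max_count = length - 1
    # state[prev_is_p, count]
    state = np.zeros((2, max_count + 1))
    state[1, 0] = f_p
    state[0, 0] = 1 - f_p
    for _ in range(length - 1):
        new = np.zeros_like(state)
        # next letter not P: count unchanged, prev flag 0
        new[0, :] = (state[0, :] + state[1, :]) * (1 - f_p)
        # next letter P after non-P: count unchanged
        new[1, :] += state[0, :] * f_p
        # next letter P after P: count + 1
        new[1, 1:] += state[1, :-1] * f_p
        state = new
    return state.sum(axis=0)


def pp_total_count_distribution(lengths: Sequence[int], f_p: float) -> np.ndarray:
    """PMF of the summed count over independent sequences (convolution)."""
    pmf = np.ones(1)
    for length in lengths:
        pmf = np.convolve(pmf, pp_count_distribution(length, f_p))
    return pmf


def markov_word_test(
    n_obs: int,
    expectation: float,
    variance: float,
    lengths: Sequence[int] | None = None,
    f_p: float | None = None,
    exact_threshold: int = 2000,
) -> dict:
    """Significance of the observed "PP" count under the M0 null.

    Below ``exact_threshold`` total length (and when ``lengths``/``f_p`` are
    given) the p-values come from the exact DP count distribution; otherwise
    from a Gaussian approximation with continuity correction.  Returns a
    dict with z, p_depletion, p_enrichment, p_two_sided and the branch used.
    """
    total_len = sum(lengths) if lengths is not None else None
    if (
        lengths is not None
        and f_p is not None
        and total_len <= exact_threshold
    ):
        pmf = pp_total_count_distribution(lengths, f_p)
        cdf = np.cumsum(pmf)
        k = min(n_obs, len(pmf) - 1)
        p_dep = float(cdf[k]) if n_obs < len(pmf) else 1.0
        p_enr = float(pmf[k:].sum()) if n_obs < len(pmf) else 0.0
        sd = np.sqrt(variance) if variance > 0 else float("nan")
        z = (n_obs - expectation) / sd if variance > 0 else float("nan")
        branch = "exact"
    else:
        if variance <= 0:
            raise ValueError("variance must be positive for the Gaussian branch")
        sd = np.sqrt(variance)
        z = (n_obs - expectation) / sd
        # continuity correction toward the null
        p_dep = float(stats.norm.cdf((n_obs + 0.5 - expectation) / sd))
        p_enr = float(stats.norm.sf((n_obs - 0.5 - expectation) / sd))
        branch = "gaussian"
    p_two = min(1.0, 2 * min(p_dep, p_enr))
    return {
        "z": float(z),
        "p_depletion": p_dep,
        "p_enrichment": p_enr,
        "p_two_sided": p_two,
        "branch": branch,
    }


def markov_fold_change(
    sequences: Sequence[str],
    motif_counter: Callable[[str], int] | None = None,
    null: MarkovNull | None = None,
    alternative: str = "two-sided",
    exact_threshold: int = 2000,
) -> FoldChangeResult:
    """Fold change of the observed "PP" word count against the Markov M0
    expectation.

    Both sides of the ratio use overlapping word occurrences (the essential
    part of the motif is the proline stretch); the null is estimated from
    the analysed sequences themselves unless one is supplied.
    """
    counter = motif_counter or count_pp_words
    n_obs = int(sum(counter(s) for s in sequences))
    if null is None:
        null = MarkovNull.from_sequences(sequences, source="analysed sequences")
    lengths = [len(s) for s in sequences if len(s) >= 2]
    if not lengths:
        raise ValueError("no sequences of length >= 2")
    expectation, variance = markov_expected_count(lengths, null)
    if expectation == 0.0:
        return FoldChangeResult(
            n_obs=n_obs, n_exp=0.0, fold_change=float("nan"), p_value=float("nan"),
            null_kind="MARKOV_M0", alternative=alternative, variance=variance, degenerate=True,
        )
    test = markov_word_test(
        n_obs, expectation, variance, lengths=lengths, f_p=null.f_p,
        exact_threshold=exact_threshold,
    )
    key = {"depletion": "p_depletion", "enrichment": "p_enrichment", "two-sided": "p_two_sided"}[alternative]
    return FoldChangeResult(
        n_obs=n_obs,
        n_exp=expectation,
        fold_change=n_obs / expectation,
        p_value=test[key],
        null_kind="MARKOV_M0",
        alternative=alternative,
        variance=variance,
        branch=test["branch"],
    )


# ---------------------------------------------------------------------------
# Word-frequency table and vector comparison


def dimer_ratio_table(proteome: Sequence[str]) -> pd.DataFrame:
    """Observed/expected frequency ratio for all 400 amino-acid dimers.

    Observed dimer frequencies use overlapping windows within each sequence
    (no cross-sequence dimers); expected = product of single-letter
    frequencies.
    """
    if not proteome:
        raise ValueError("empty proteome")
    letters = sorted({ch for seq in proteome for ch in seq})
    idx = {ch: i for i, ch in enumerate(letters)}
    k = len(letters)
    single = np.zeros(k)
    dimer = np.zeros((k, k))
    for seq in proteome:
        codes = np.array([idx[c] for c in seq])
        np.add.at(single, codes, 1)
        if len(codes) >= 2:
            np.add.at(dimer, (codes[:-1], codes[1:]), 1)
    f_single = single / single.sum()
    f_dimer = dimer / dimer.sum()
    expected = np.outer(f_single, f_single)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, f_dimer / expected, np.nan)
    rows = [
        {
            "dimer": a + b,
            "observed_freq": f_dimer[i, j],
            "expected_freq": expected[i, j],
            "ratio": ratio[i, j],
        }
        for i, a in enumerate(letters)
        for j, b in enumerate(letters)
    ]
    return pd.DataFrame(rows).set_index("dimer")


def compare_fold_change_vectors(ratios_a: np.ndarray, ratios_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value between two ratio vectors."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both vectors must have at least one finite value")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
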