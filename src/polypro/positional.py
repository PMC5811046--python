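"""Positional analyses of motif occurrence.

Three families of analyses locate polyproline motifs relative to landmarks
of the protein:

* the N-terminal ramp — motif occurrence in the first ``split`` (default
  50) residues vs the remainder, each normalised by its own shuffle null;
* structural domains — depletion inside domains, enrichment in inter-domain
  linkers and in windows bracketing domain boundaries, profiled relative to
  domain starts/ends;
* transmembrane helices (TMHs) — profiles relative to the TMH start and
  enrichment tests in four sites (I: -17..-1, II: +23..+32, III: +49..+59,
  IV: +77..+87 relative to the TMH start), each site instance labelled by
  whether its midpoint lies inside an annotated TMH.

All coordinates are 1-based inclusive; profile offset 0 is the anchor
residue itself.  A motif's position is its anchor (first proline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import (
    FoldChangeResult,
    MarkovNull,
    compare_fold_change_vectors,
    per_sequence_fold_changes,
)

DOMAIN = "DOMAIN"
TMH = "TMH"

#: Site windows relative to the TMH start (offset 0 = first TMH residue).
DEFAULT_TMH_SITES = {"I": (-17, -1), "II": (23, 32), "III": (49, 59), "IV": (77, 87)}


@dataclass
class AnnotationTrack:
    """Per-protein landmark intervals (domains or TMHs), 1-based inclusive."""

    kind: str  # DOMAIN | TMH
    intervals: dict[str, list[tuple[int, int]]]  # protein_id -> sorted intervals

    def validate(self, proteome: Mapping[str, str] | None = None) -> "AnnotationTrack":
        for pid, ivs in self.intervals.items():
            prev_end = 0
            for start, end in ivs:
                if not (1 <= start <= end):
                    raise ValueError(f"bad interval ({start},{end}) for {pid}")
                if start <= prev_end:
                    raise ValueError(f"overlapping {self.kind} intervals for {pid}")
                if proteome is not None and pid in proteome and end > len(proteome[pid]):
                    raise ValueError(f"interval beyond sequence end for {pid}")
                prev_end = end
        return self


@dataclass
class PositionalProfile:
    """Motif frequency around an anchor class, with 3-residue smoothing."""

    anchor_kind: str  # PROTEIN_START | DOMAIN_START | DOMAIN_END | TMH_START
    offsets: np.ndarray
    raw_counts: np.ndarray
    n_contributing: np.ndarray
    frequency: np.ndarray
    smoothed: np.ndarray


def smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average; edges average the available points."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - 1), min(len(v), i + 2)
        out[i] = v[lo:hi].mean()
    return out


def _anchors_per_protein(motif_table: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        pid: grp["start"].to_numpy()
        for pid, grp in motif_table.groupby("protein_id")
    }


def nterminal_ramp_test(
    proteome: Mapping[str, str],
    motif_table: pd.DataFrame,
    split: int = 50,
    replicates: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare motif occurrence in residues 1..split vs the remainder.

    Each protein is cut at ``split``; a motif belongs to the segment
    containing its anchor.  Each segment is shuffle-normalised within
    itself (one fold change per segment: observed / mean shuffled count)
    and the two per-segment vectors compared by rank-sum test.
    """
    if split < 1:
        raise ValueError("split must be >= 1")
    anchors = _anchors_per_protein(motif_table)
    nterm_segments, rest_segments = [], []
    n_nterm_obs = n_rest_obs = 0
    for pid, seq in sorted(proteome.items()):
        nterm_segments.append(seq[:split])
        # the remainder is cut into complete split-length tiles so that the
        # two compared populations have identical length distributions; a
        # rank-sum test between count ratios of unequal-length segments is
        # not calibrated (their discreteness differs)
        for k in range(split, len(seq) - split + 1, split):
            rest_segments.append(seq[k : k + split])
        for a in anchors.get(pid, ()):
            if a <= split:
                n_nterm_obs += 1
            else:
                n_rest_obs += 1
    result = {"n_nterm_obs": n_nterm_obs, "n_rest_obs": n_rest_obs}
    if not rest_segments:
        result.update({"fc_nterm": np.nan, "fc_rest": np.nan,
                       "p_ranksum": np.nan, "flagged": True})
        return result
    vec_nterm = per_sequence_fold_changes(nterm_segments, replicates=replicates, seed=seed)
    vec_rest = per_sequence_fold_changes(rest_segments, replicates=replicates, seed=seed + 1)
    result.update(
        {
            "fc_nterm": float(np.nanmean(vec_nterm)),
            "fc_rest": float(np.nanmean(vec_rest)),
            "p_ranksum": compare_fold_change_vectors(vec_nterm, vec_rest),
            "flagged": False,
        }
    )
    return result


def define_linkers(
    domains: Sequence[tuple[int, int]], protein_length: int
) -> list[tuple[int, int]]:
    """Inter-domain linkers between consecutive domains.

    Linker between a domain ending at e and the next starting at s is
    [e+1, s-1]; when shorter than 5 residues it is extended downstream
    (into the next domain) to length 5, clipped at the protein end.
    """
    ivs = sorted(domains)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError("overlapping domains")
    linkers = []
    for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
        start, end = e1 + 1, s2 - 1
        if end - start + 1 < 5:
            end = min(start + 4, protein_length)
        linkers.append((start, end))
    return linkers


def extract_segments(
    proteome: Mapping[str, str],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Subsequences (and their coordinates) for the given intervals."""
    segments, coords = [], []
    for pid in sorted(intervals):
        seq = proteome[pid]
        for start, end in intervals[pid]:
            segments.append(seq[start - 1 : end])
            coords.append((pid, start, end))
    return segments, coords


def region_enrichment(
    proteome: Mapping[str, str],
    motif_table: pd.DataFrame,
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    null: MarkovNull | None = None,
    alternative: str = "two-sided",
) -> FoldChangeResult:
    """Markov-M0 fold change of motif occurrence within a set of regions.

    Observed = overlapping "PP" word count inside the extracted segments
    (the same semantics as the M0 expectation, so an i.i.d. segment set has
    fold change 1); composition is estimated from the segments themselves
    unless a null is given.  ``motif_table`` is consulted only for the
    anchors diagnostic (count of motif anchors inside the regions).
    """
    from .nulls import count_pp_words

    segments, coords = extract_segments(proteome, intervals)
    if not segments:
        raise ValueError("empty segment set")
    anchors = _anchors_per_protein(motif_table)
    n_anchor_obs = 0
    for pid, start, end in coords:
        for a in anchors.get(pid, ()):
            if start <= a <= end:
                n_anchor_obs += 1
    n_obs = int(sum(count_pp_words(s) for s in segments))
    if null is None:
        null = MarkovNull.from_sequences(segments, source="region segments")
    lengths = [len(s) for s in segments if len(s) >= 2]
    from .nulls import markov_expected_count, markov_word_test

    expectation, variance = markov_expected_count(lengths, null)
    if expectation == 0.0:
        return FoldChangeResult(
            n_obs=n_obs, n_exp=0.0, fold_change=float("nan"), p_value=float("nan"),
            null_kind="MARKOV_M0", alternative=alternative, variance=variance, degenerate=True,
        )
    test = markov_word_test(n_obs, expectation, variance, lengths=lengths, f_p=null.f_p)
    key = {"depletion": "p_depletion", "enrichment": "p_enrichment",
           "two-sided": "p_two_sided"}[alternative]
    return FoldChangeResult(
        n_obs=n_obs, n_exp=expectation, fold_change=n_obs / expectation,
        p_value=test[key], null_kind="MARKOV_M0", alternative=alternative,
        variance=variance, branch=test["branch"],
    )


def boundary_profile(
    proteome: Mapping[str, str],
    motif_table: pd.DataFrame,
    track: AnnotationTrack,
    anchor_kind: str,
    offsets: tuple[int, int] | None = None,
) -> PositionalProfile:
    """Motif frequency at each offset around domain/TMH anchors.

    For every anchor instance, each motif anchor in the same protein
    contributes at offset = motif position - anchor position (negative =
    upstream).  Frequencies are normalised by the number of anchor
    instances whose sequence covers the offset, then smoothed over a
    3-residue window.
    """
    if offsets is None:
        offsets = (-20, 90) if anchor_kind == "TMH_START" else (-25, 25)
    lo, hi = offsets
    offs = np.arange(lo, hi + 1)
    raw = np.zeros(len(offs), dtype=int)
    contributing = np.zeros(len(offs), dtype=int)
    anchors = _anchors_per_protein(motif_table)
    for pid, ivs in sorted(track.intervals.items()):
        if pid not in proteome:
            continue
        length = len(proteome[pid])
        motif_pos = anchors.get(pid, ())
        for start, end in ivs:
            if anchor_kind in ("DOMAIN_START", "TMH_START"):
                anchor = start
            elif anchor_kind == "DOMAIN_END":
                anchor = end
            else:
                raise ValueError(f"unknown anchor kind {anchor_kind!r}")
            covered = (anchor + offs >= 1) & (anchor + offs <= length)
            contributing += covered
            for a in motif_pos:
                off = a - anchor
                if lo <= off <= hi:
                    raw[off - lo] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(contributing > 0, raw / contributing, 0.0)
    return PositionalProfile(
        anchor_kind=anchor_kind,
        offsets=offs,
        raw_counts=raw,
        n_contributing=contributing,
        frequency=freq,
        smoothed=smooth3(freq),
    )


def tmh_site_analysis(
    proteome: Mapping[str, str],
    motif_table: pd.DataFrame,
    tmh_track: AnnotationTrack,
    sites: Mapping[str, tuple[int, int]] = DEFAULT_TMH_SITES,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-site, per-location (TMH / non-TMH) Markov-M0 enrichment tests.

    For every TMH instance and site, the site's absolute interval is placed
    relative to that TMH's start; instances extending beyond the protein are
    dropped; an instance is labelled TMH when its midpoint residue lies
    inside any annotated TMH of the protein.
    """
    if not tmh_track.intervals:
        raise ValueError("TMH track is empty")
    grouped: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    counts: dict[tuple[str, str], int] = {}
    for pid, ivs in sorted(tmh_track.intervals.items()):
        if pid not in proteome:
            continue
        length = len(proteome[pid])
        for tmh_start, _ in ivs:
            for site, (rel_lo, rel_hi) in sites.items():
                abs_lo = tmh_start + rel_lo
                abs_hi = tmh_start + rel_hi
                if abs_lo < 1 or abs_hi > length:
                    continue
                mid = (abs_lo + abs_hi) // 2
                in_tmh = any(s <= mid <= e for s, e in ivs)
                key = (site, TMH if in_tmh else "non-TMH")
                grouped.setdefault(key, {}).setdefault(pid, []).append((abs_lo, abs_hi))
                counts[key] = counts.get(key, 0) + 1
    rows = []
    for (site, label), intervals in sorted(grouped.items()):
        res = region_enrichment(proteome, motif_table, intervals, alternative=alternative)
        rows.append(
            {
                "site": site,
                "location": label,
                "n_instances": counts[(site, label)],
                "n_obs": res.n_obs,
                "n_exp": res.n_exp,
                "fold_change": res.fold_change,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def tp_proportion_test(
    tp_ids: Sequence[str], soluble_ids: Sequence[str], motif_table: pd.DataFrame
) -> dict:
    """Chi-squared test (no continuity correction) of the proportion of
    motif-bearing proteins among transmembrane vs soluble proteins."""
    tp_set, sol_set = set(tp_ids), set(soluble_ids)
    if tp_set & sol_set:
        raise ValueError("tp_ids and soluble_ids overlap")
    if not tp_set or not sol_set:
        raise ValueError("both id sets must be non-empty")
    with_motif = set(motif_table["protein_id"])
    a = len(tp_set & with_motif)
    b = len(tp_set) - a
    c = len(sol_set & with_motif)
    d = len(sol_set) - c
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return {
        "tp_with_motif": a,
        "tp_total": len(tp_set),
        "tp_fraction": a / len(tp_set),
        "soluble_with_motif": c,
        "soluble_total": len(sol_set),
        "soluble_fraction": c / len(sol_set),
        "chi2": float(chi2),
        "p_value": float(p),
    }
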