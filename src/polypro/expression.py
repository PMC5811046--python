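"""Translation efficiency and its relation to motif density.

Translation efficiency of a gene is its protein abundance divided by its
transcription level.  A negative rank correlation between translation
efficiency (or abundance) and polyproline-motif density is the signature of
translation-efficiency-driven selection against stalling.  Predicted motif
strengths are also checked for concordance with ribosome-profiling stall
rankings (asymmetry scores).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def translation_efficiency(abundance: float, transcription: float) -> float:
    """Protein abundance divided by transcription level."""
    if transcription <= 0:
        raise ValueError("transcription level must be positive")
    if abundance < 0:
        raise ValueError("abundance must be nonnegative")
    return abundance / transcription


def expression_table(
    abundance: Mapping[str, float], transcription: Mapping[str, float]
) -> pd.DataFrame:
    """Join the two datasets on their shared genes and compute efficiency."""
    genes = sorted(set(abundance) & set(transcription))
    rows = [
        {
            "gene_id": g,
            "protein_abundance": abundance[g],
            "transcription_level": transcription[g],
            "translation_efficiency": translation_efficiency(abundance[g], transcription[g]),
        }
        for g in genes
    ]
    return pd.DataFrame(rows)


def motif_density(protein_length: int, n_motifs: int) -> float:
    """Motifs per 100 residues."""
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    return 100.0 * n_motifs / protein_length


def motif_density_table(
    proteome: Mapping[str, str], motif_counts: Mapping[str, int]
) -> pd.Series:
    return pd.Series(
        {
            pid: motif_density(len(seq), int(motif_counts.get(pid, 0)))
            for pid, seq in sorted(proteome.items())
        },
        name="motif_density",
    )


def correlate_expression_motifs(
    records: pd.DataFrame,
    densities: Mapping[str, float],
    measure: str = "TE",
    n_bins: int = 4,
) -> dict:
    """Spearman correlation between an expression measure and motif density.

    ``measure`` is "TE" (translation efficiency) or "ABUNDANCE".  Also
    returns a quantile-binned summary (mean density per expression bin) for
    plotting.  All-constant input is flagged with rho = NaN.
    """
    col = {"TE": "translation_efficiency", "ABUNDANCE": "protein_abundance"}[measure]
    matched = records[records["gene_id"].isin(densities)]
    if len(matched) < 3:
        raise ValueError("need at least 3 paired observations")
    x = matched[col].to_numpy(dtype=float)
    y = np.array([densities[g] for g in matched["gene_id"]], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(x),
                "flagged": True, "bins": None}
    rho, p = stats.spearmanr(x, y)
    order = pd.qcut(pd.Series(x).rank(method="first"), n_bins, labels=False)
    bins = (
        pd.DataFrame({"bin": order, "density": y})
        .groupby("bin")["density"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return {"rho": float(rho), "p_value": float(p), "n": len(x),
            "flagged": False, "bins": bins}


def profiling_concordance(
    stall_scores: Mapping[str, float],
    strong_medium_genes: Sequence[str],
    threshold: float,
) -> dict:
    """Fraction of genes above the stall-score threshold that carry at
    least one medium-or-strong motif.

    ``stall_scores`` are ribosome-profiling asymmetry ratios; genes absent
    from ``strong_medium_genes`` count as lacking such motifs.  An empty
    above-threshold set is flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = [g for g, s in stall_scores.items() if s >= threshold]
    if not above:
        return {"threshold": threshold, "n_above": 0, "fraction": float("nan"),
                "flagged": True}
    carriers = set(strong_medium_genes)
    k = sum(1 for g in above if g in carriers)
    return {
        "threshold": threshold,
        "n_above": len(above),
        "n_with_motif": k,
        "fraction": k / len(above),
        "flagged": False,
    }


def concordance_table(
    stall_scores: Mapping[str, float],
    strong_medium_genes: Sequence[str],
    thresholds: Sequence[float] = (2.0, 3.0, 5.0),
) -> pd.DataFrame:
    return pd.DataFrame(
        [profiling_concordance(stall_scores, strong_medium_genes, t) for t in thresholds]
    )
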