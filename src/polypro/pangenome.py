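"""Core/accessory pan-proteome partitioning and motif-occurrence comparison.

A protein belongs to the *core* proteome when its orthologous group has at
least one member in every strain of the analysed set; members of all other
groups, and proteins assigned to no group at all, form the *accessory*
proteome.  The core proteome contains the evolutionarily older, conserved
sequences, so a lower motif occurrence there is the signature of selection
against ribosome stalling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import StrengthClass
from .nulls import compare_fold_change_vectors, per_sequence_fold_changes

CORE = "CORE"
ACCESSORY = "ACCESSORY"


@dataclass
class CoreAccessoryAssignment:
    """Per-protein CORE/ACCESSORY labels plus per-strain summary counts."""

    labels: pd.Series  # index protein_id -> CORE | ACCESSORY
    per_strain: pd.DataFrame  # index strain, columns n_core, n_accessory


def partition_core_accessory(
    og_table: pd.DataFrame,
    strain_set: Sequence[str],
    proteomes: Mapping[str, Mapping[str, str]],
) -> CoreAccessoryAssignment:
    """Label every protein of every input proteome CORE or ACCESSORY.

    ``og_table`` has one row per group membership, columns
    (og_id, strain, protein_id).  A group is core iff it has >=1 member in
    every strain of ``strain_set``.
    """
    if not len(strain_set):
        raise ValueError("strain_set must be non-empty")
    strain_set = list(strain_set)
    known = {pid for prot in proteomes.values() for pid in prot}
    missing = sorted(set(og_table["protein_id"]) - known)
    if missing:
        raise ValueError(f"orthology members absent from proteomes: {missing[:5]}")
    dup = og_table.groupby("protein_id")["og_id"].nunique()
    multi = dup[dup > 1]
    if len(multi):
        raise ValueError(f"proteins in more than one group: {sorted(multi.index)[:5]}")

    strains_per_group = og_table.groupby("og_id")["strain"].agg(set)
    required = set(strain_set)
    core_groups = set(strains_per_group[strains_per_group.apply(lambda s: required <= s)].index)
    core_proteins = set(og_table.loc[og_table["og_id"].isin(core_groups), "protein_id"])

    labels = {}
    summary = []
    for strain, prot in sorted(proteomes.items()):
        n_core = 0
        for pid in prot:
            is_core = pid in core_proteins
            labels[pid] = CORE if is_core else ACCESSORY
            n_core += is_core
        summary.append({"strain": strain, "n_core": n_core, "n_accessory": len(prot) - n_core})
    return CoreAccessoryAssignment(
        labels=pd.Series(labels, name="label").sort_index(),
        per_strain=pd.DataFrame(summary).set_index("strain"),
    )


def stratum_counter(rules, stratum: StrengthClass | None):
    """Counter of motifs of one strength class (None = all, incl. ambiguous).

    Scans and classifies the sequence it is given, so it applies equally to
    real and shuffled sequences.
    """
    from .motifs import classify_motif, scan_motifs
    from .nulls import default_pp_counter

    if stratum is None:
        return default_pp_counter

    def counter(sequence: str) -> int:
        return sum(
            1
            for m in scan_motifs(sequence, "_")
            if classify_motif(m, rules) == stratum
        )

    return counter


def compare_core_accessory_occurrence(
    assignment: CoreAccessoryAssignment,
    proteomes: Mapping[str, Mapping[str, str]],
    rules,
    strata: Sequence[StrengthClass | None] = (None,),
    replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per strain and per strength stratum: shuffle-normalized fold-change
    vectors for the CORE and ACCESSORY subsets, compared by rank-sum test.

    ``strata`` entries are StrengthClass values, or None for all motifs
    pooled.  Replicate counts re-scan and re-classify the shuffled
    sequences, so observed and expected counts use identical semantics.
    The compared vectors hold one fold change per protein (observed /
    mean shuffled count), keeping the rank-sum test calibrated under
    equal motif densities.  Strains are compared independently; empty
    strata are flagged.
    """
    rows = []
    for strain, prot in sorted(proteomes.items()):
        core_seqs = [s for pid, s in sorted(prot.items()) if assignment.labels[pid] == CORE]
        acc_seqs = [s for pid, s in sorted(prot.items()) if assignment.labels[pid] == ACCESSORY]
        for stratum in strata:
            label = stratum.label if stratum is not None else "ALL"
            counter = stratum_counter(rules, stratum)
            n_core = int(sum(counter(s) for s in core_seqs))
            n_acc = int(sum(counter(s) for s in acc_seqs))
            row = {"strain": strain, "stratum": label, "n_core_obs": n_core, "n_accessory_obs": n_acc}
            if not core_seqs or not acc_seqs or n_core == 0 or n_acc == 0:
                row.update({"fc_core": np.nan, "fc_accessory": np.nan, "p_ranksum": np.nan, "flagged": True})
                rows.append(row)
                continue
            vec_core = per_sequence_fold_changes(core_seqs, counter if stratum else None,
                                                 replicates=replicates, seed=seed)
            vec_acc = per_sequence_fold_changes(acc_seqs, counter if stratum else None,
                                                replicates=replicates, seed=seed + 1)
            row.update(
                {
                    "fc_core": float(np.nanmean(vec_core)),
                    "fc_accessory": float(np.nanmean(vec_acc)),
                    "p_ranksum": compare_fold_change_vectors(vec_core, vec_acc),
                    "flagged": False,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
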