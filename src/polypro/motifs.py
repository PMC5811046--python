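"""Detection and strength classification of polyproline ribosome-stalling motifs.

A polyproline motif is a maximal run of >=2 consecutive prolines together
with its flanking context X(-2) X(-1) - nP - X(+1).  Consecutive prolines
stall the ribosome during translation; the severity of the stall (strong,
medium or weak arrest) depends on the run length and on the identity of the
flanking residues.  This module finds every such motif in a protein
sequence and predicts its arrest strength from a rule table mapping flank
residues to effect classes and flank-effect combinations to strength
classes.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel for a flank position that falls outside the sequence.
MISSING = ""


class StrengthClass(enum.IntEnum):
    """Predicted ribosome-stalling arrest strength, totally ordered by rank."""

    NONE = 0
    WEAK = 1
    MEDIUM = 2
    STRONG = 3

    @property
    def label(self) -> str:
        return self.name


#: Returned by :func:`classify_motif` when a present flank letter is not one
#: of the 20 standard amino acids; such motifs are kept in raw occurrence
#: counts but excluded from strength-stratified analyses.
UNCLASSIFIED_AMBIGUOUS = "AMBIGUOUS"


class FlankEffect(enum.IntEnum):
    """Effect class a flanking residue exerts on stalling strength."""

    WEAK_EFF = 1
    MEDIUM_EFF = 2
    STRONG_EFF = 3


@dataclass(frozen=True)
class PolyprolineMotif:
    """A maximal proline stretch with flanking context.

    ``start`` is the 1-based position of the first proline; ``n`` the number
    of consecutive prolines; ``x_m2``/``x_m1``/``x_p1`` the flank letters
    (``MISSING`` at a sequence boundary).  ``anchor`` (= ``start``) is the
    position used by positional analyses.
    """

    protein_id: str
    start: int
    n: int
    x_m2: str
    x_m1: str
    x_p1: str
    strength: StrengthClass | str | None = None

    @property
    def anchor(self) -> int:
        return self.start

    @property
    def end(self) -> int:
        """1-based inclusive position of the last proline."""
        return self.start + self.n - 1


class RuleTableError(ValueError):
    """Raised when a strength rule table fails validation."""


@dataclass
class StrengthRuleTable:
    """Lookup encoding flank-residue effect classes and combination rules.

    ``flank_effect[pos][letter]`` gives the :class:`FlankEffect` of ``letter``
    at position ``pos`` in {"x_m2", "x_m1", "x_p1"}.  ``combination_rules``
    maps ``(n_category, eff_m2, eff_m1, eff_p1)`` to a :class:`StrengthClass`,
    where ``n_category`` is ``"2"`` or ``"3+"``.
    """

    flank_effect: dict[str, dict[str, FlankEffect]]
    combination_rules: dict[tuple[str, FlankEffect, FlankEffect, FlankEffect], StrengthClass]
    provenance: str = ""
    _validated: bool = field(default=False, repr=False)

    POSITIONS = ("x_m2", "x_m1", "x_p1")
    N_CATEGORIES = ("2", "3+")

    def validate(self) -> "StrengthRuleTable":
        missing: list[str] = []
        for pos in self.POSITIONS:
            table = self.flank_effect.get(pos, {})
            for aa in STANDARD_AA:
                if aa not in table:
                    missing.append(f"flank_effect[{pos}][{aa}]")
        effects = list(FlankEffect)
        for ncat in self.N_CATEGORIES:
            for e2 in effects:
                for e1 in effects:
                    for ep in effects:
                        if (ncat, e2, e1, ep) not in self.combination_rules:
                            missing.append(
                                f"rule[n={ncat},m2={e2.name},m1={e1.name},p1={ep.name}]"
                            )
        if missing:
            raise RuleTableError(
                "rule table incomplete; missing entries: " + ", ".join(missing[:20])
                + ("..." if len(missing) > 20 else "")
            )
        self._validated = True
        return self


# Neutral flank effects used when a flank is MISSING (motif at a terminus):
# at X(-1)/X(+1) the weak-effect class contributes nothing to the arrest; at
# X(-2), whose effect classes act as promote/attenuate modifiers, the neutral
# choice is the medium (no-modulation) class.
_NEUTRAL_EFFECT = {
    "x_m2": FlankEffect.MEDIUM_EFF,
    "x_m1": FlankEffect.WEAK_EFF,
    "x_p1": FlankEffect.WEAK_EFF,
}


def default_combination_rules() -> dict[tuple, StrengthClass]:
    """Build the full combination grid from the base rules.

    n>=3: the proline run is itself a strong arrest element -> STRONG.
    n=2: start from the stronger of the X(-1)/X(+1) effects, promote one
    rank for a strong-effect X(-2) ("further pronounce the arrest"), demote
    one rank for a weak-effect X(-2) ("attenuate it"), clamped to
    [WEAK, STRONG].
    """
    rules: dict[tuple, StrengthClass] = {}
    effects = list(FlankEffect)
    for e2 in effects:
        for e1 in effects:
            for ep in effects:
                rules[("3+", e2, e1, ep)] = StrengthClass.STRONG
                base = max(int(e1), int(ep))  # FlankEffect rank == class rank
                if e2 is FlankEffect.STRONG_EFF:
                    base += 1
                elif e2 is FlankEffect.WEAK_EFF:
                    base -= 1
                base = min(max(base, int(StrengthClass.WEAK)), int(StrengthClass.STRONG))
                rules[("2", e2, e1, ep)] = StrengthClass(base)
    return rules


def scan_motifs(sequence: str, protein_id: str = "") -> list[PolyprolineMotif]:
    """Find every maximal run of >=2 prolines, left to right.

    Flanks are populated from the sequence or set to ``MISSING`` at the
    boundaries.  Strength is left unset.
    """
    if not sequence:
        raise ValueError(f"empty sequence for protein {protein_id!r}")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_p = arr == ord("P")
    # run starts: P at i, and (i == 0 or not P at i-1)
    starts = np.flatnonzero(is_p & ~np.concatenate(([False], is_p[:-1])))
    ends = np.flatnonzero(is_p & ~np.concatenate((is_p[1:], [False])))
    motifs: list[PolyprolineMotif] = []
    for s0, e0 in zip(starts, ends):
        n = int(e0 - s0 + 1)
        if n < 2:
            continue
        motifs.append(
            PolyprolineMotif(
                protein_id=protein_id,
                start=int(s0) + 1,
                n=n,
                x_m2=sequence[s0 - 2] if s0 >= 2 else MISSING,
                x_m1=sequence[s0 - 1] if s0 >= 1 else MISSING,
                x_p1=sequence[e0 + 1] if e0 + 1 < len(sequence) else MISSING,
            )
        )
    return motifs


def count_pp_runs(is_p: np.ndarray) -> int:
    """Number of maximal runs of >=2 True values (vectorised fast path)."""
    if is_p.size < 2:
        return 0
    prev = np.concatenate(([False], is_p[:-1]))
    nxt = np.concatenate((is_p[1:], [False]))
    # start of a run of length >=2: P here, no P before, P after
    return int(np.count_nonzero(is_p & ~prev & nxt))


def classify_motif(
    motif: PolyprolineMotif, rules: StrengthRuleTable
) -> StrengthClass | str:
    """Predict the arrest strength of a motif from the rule table.

    Returns ``UNCLASSIFIED_AMBIGUOUS`` when any present flank letter lies
    outside the 20 standard amino acids.  MISSING flanks take the neutral
    effect class for their position.
    """
    if not rules._validated:
        raise RuleTableError("rule table must be validated before use")
    flanks = {"x_m2": motif.x_m2, "x_m1": motif.x_m1, "x_p1": motif.x_p1}
    effects = {}
    for pos, letter in flanks.items():
        if letter == MISSING:
            effects[pos] = _NEUTRAL_EFFECT[pos]
        elif letter in STANDARD_AA:
            effects[pos] = rules.flank_effect[pos][letter]
        else:
            return UNCLASSIFIED_AMBIGUOUS
    ncat = "2" if motif.n == 2 else "3+"
    return rules.combination_rules[(ncat, effects["x_m2"], effects["x_m1"], effects["x_p1"])]


MOTIF_TABLE_COLUMNS = ["protein_id", "start", "n", "x_m2", "x_m1", "x_p1", "strength"]


def scan_proteome(
    proteome: Mapping[str, str] | Iterable[tuple[str, str]],
    rules: StrengthRuleTable,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan and classify every protein; return (motif table, per-protein counts).

    The motif table has one row per motif, sorted by (protein_id, start);
    the counts Series covers every protein, including zero-motif ones.
    """
    items = list(proteome.items()) if isinstance(proteome, Mapping) else list(proteome)
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate protein ids: {dupes[:5]}")
    rows = []
    counts = {}
    for pid, seq in sorted(items):
        ms = scan_motifs(seq, pid)
        counts[pid] = len(ms)
        for m in ms:
            strength = classify_motif(m, rules)
            label = strength.label if isinstance(strength, StrengthClass) else strength
            rows.append((pid, m.start, m.n, m.x_m2, m.x_m1, m.x_p1, label))
    table = pd.DataFrame(rows, columns=MOTIF_TABLE_COLUMNS)
    return table, pd.Series(counts, name="n_motifs").sort_index()


# ---------------------------------------------------------------------------
# Rule table serialization


def _table_to_dict(table: StrengthRuleTable) -> dict:
    return {
        "provenance": table.provenance,
        "flank_effect": {
            pos: {aa: eff.name for aa, eff in sorted(table.flank_effect[pos].items())}
            for pos in StrengthRuleTable.POSITIONS
        },
        "combination_rules": [
            {
                "n": ncat,
                "x_m2": e2.name,
                "x_m1": e1.name,
                "x_p1": ep.name,
                "strength": cls.label,
            }
            for (ncat, e2, e1, ep), cls in sorted(
                table.combination_rules.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
            )
        ],
    }


def save_rule_table(table: StrengthRuleTable, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_table_to_dict(table), fh, sort_keys=False)


def load_rule_table(path) -> StrengthRuleTable:
    """Load and validate a strength rule table from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        flank_effect = {
            pos: {aa: FlankEffect[eff] for aa, eff in doc["flank_effect"][pos].items()}
            for pos in StrengthRuleTable.POSITIONS
        }
        combo = {
            (
                str(r["n"]),
                FlankEffect[r["x_m2"]],
                FlankEffect[r["x_m1"]],
                FlankEffect[r["x_p1"]],
            ): StrengthClass[r["strength"]]
            for r in doc["combination_rules"]
        }
    except KeyError as exc:
        raise RuleTableError(f"malformed rule table {path}: missing {exc}") from exc
    table = StrengthRuleTable(
        flank_effect=flank_effect,
        combination_rules=combo,
        provenance=doc.get("provenance", ""),
    )
    return table.validate()


def default_rule_table() -> StrengthRuleTable:
    """The packaged default rule table (synthetic reconstruction; see file)."""
    ref = importlib.resources.files("polypro.data") / "stalling_rules_synthetic.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_rule_table(path)
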