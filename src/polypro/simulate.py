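"""Synthetic data generators with recorded ground truth.

Every analysis stage in this package can be exercised without external
downloads: these generators emit proteomes, pan-genomes, orthologous-group
trees with evolved stalling-state histories, domain/TMH annotation tracks
and expression tables with the statistical structure the analyses assume,
alongside machine-readable ground truth.  A seed fully determines every
output.

Default parameters mirror the analysed study system: 43 strains of a few
thousand proteins each, lognormal protein lengths around 270 residues, a
bacterial amino-acid composition with proline frequency ~0.044, 1,000
shuffle replicates upstream.  Analyses on synthetic data typically override
the sizes downwards.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from dendropy.simulate import treesim

from .motifs import (
    STANDARD_AA,
    PolyprolineMotif,
    StrengthClass,
    StrengthRuleTable,
    classify_motif,
    scan_motifs,
)

#: Approximate E. coli amino-acid composition (normalised on use).
ECOLI_AA_FREQS = {
    "A": 0.095, "R": 0.055, "N": 0.039, "D": 0.051, "C": 0.012,
    "E": 0.057, "Q": 0.044, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.105, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.014, "Y": 0.028, "V": 0.070,
}

#: Flank contexts that realise each strength class under the packaged rules.
#: Written as (upstream letters, n prolines, downstream letter).
_PLANT_CONTEXT = {
    StrengthClass.STRONG: ("AA", 3, "V"),   # n>=3 is a strong arrest on its own
    StrengthClass.MEDIUM: ("AN", 2, "V"),   # N medium-effect at X(-1), neutral others
    StrengthClass.WEAK: ("AL", 2, "V"),     # all flank effects weak/neutral
}


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study system."""

    seed: int = 0
    n_strains: int = 43
    proteome_size: int = 4800
    length_mu: float = 5.6       # lognormal log-mean (median ~270 aa)
    length_sigma: float = 0.45
    min_length: int = 60
    aa_freqs: dict[str, float] = field(default_factory=lambda: dict(ECOLI_AA_FREQS))
    # planting program: expected planted motifs per protein, by class
    plant_per_protein: dict[StrengthClass, float] = field(default_factory=dict)
    # pan-genome program
    core_fraction: float = 0.6
    accessory_sharing_rate: float = 0.4
    unassigned_fraction: float = 0.05
    # tree / state-evolution program
    n_leaves: int = 10
    birth_rate: float = 1.0
    branch_scale: float = 0.3
    state_rate: float = 1.0      # CTMC transition rate alpha
    gain_bias: float = 1.0       # up-rate multiplier; 0 = loss-only
    root_state_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    # expression program
    target_rho: float = -0.105
    expression_noise: float = 1.0


# ---------------------------------------------------------------------------
# Proteomes with planted motifs


def _letters(rng: np.random.Generator, n: int, freqs: Mapping[str, float],
             exclude_p: bool = False) -> np.ndarray:
    letters = [aa for aa in sorted(freqs) if not (exclude_p and aa == "P")]
    probs = np.array([freqs[aa] for aa in letters], dtype=float)
    probs /= probs.sum()
    codes = np.array([ord(aa) for aa in letters], dtype=np.uint8)
    return codes[rng.choice(len(letters), size=n, p=probs)]


def _plant_at(arr: np.ndarray, pos0: int, strength: StrengthClass,
              rng: np.random.Generator, freqs: Mapping[str, float]) -> PolyprolineMotif:
    """Overwrite letters so a motif of the requested class starts at pos0
    (0-based index of the first proline).  Guards the window with non-P
    letters so the planted stretch stays maximal and isolated."""
    up, n, down = _PLANT_CONTEXT[strength]
    lo = pos0 - len(up)
    hi = pos0 + n + 1  # exclusive, includes x_p1
    window = up + "P" * n + down
    arr[lo:hi] = np.frombuffer(window.encode("ascii"), np.uint8)
    # non-P guards just outside the written window
    if lo - 1 >= 0 and arr[lo - 1] == ord("P"):
        arr[lo - 1] = _letters(rng, 1, freqs, exclude_p=True)[0]
    if hi < len(arr) and arr[hi] == ord("P"):
        arr[hi] = _letters(rng, 1, freqs, exclude_p=True)[0]
    return PolyprolineMotif(protein_id="", start=pos0 + 1, n=n,
                            x_m2=up[0], x_m1=up[1], x_p1=down, strength=strength)


def generate_sequence(
    rng: np.random.Generator,
    length: int,
    freqs: Mapping[str, float],
    plants: Sequence[StrengthClass] = (),
    window: tuple[int, int] | None = None,
) -> tuple[str, list[PolyprolineMotif]]:
    """One i.i.d. sequence with the requested motifs planted.

    ``window`` restricts planting to 1-based positions [lo, hi] (of the
    first proline).  Raises when the requested motifs cannot be packed.
    """
    arr = _letters(rng, length, freqs)
    occupied = np.zeros(length, dtype=bool)
    planted: list[PolyprolineMotif] = []
    lo = max(window[0], 3) if window else 3
    hi = min(window[1], length - 3) if window else length - 3
    for strength in plants:
        up, n, _ = _PLANT_CONTEXT[strength]
        placed = False
        for _ in range(200):
            if hi < lo:
                break
            pos0 = int(rng.integers(lo - 1, hi))  # 0-based first proline
            span = slice(max(pos0 - len(up) - 1, 0), min(pos0 + n + 2, length))
            if occupied[span].any():
                continue
            m = _plant_at(arr, pos0, strength, rng, freqs)
            occupied[span] = True
            planted.append(m)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot place a {strength.name} motif in window ({lo},{hi}) of length {length}"
            )
    return arr.tobytes().decode("ascii"), planted


def generate_proteome(
    spec: SyntheticSpec,
    rules: StrengthRuleTable,
    prefix: str = "prot",
    stream: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Proteome plus ground-truth motif table.

    Sequences are i.i.d. draws from the letter distribution; planted motifs
    (Poisson counts per protein per class from ``spec.plant_per_protein``)
    overwrite letters.  The ground truth records every motif present after
    planting — planted and incidental alike — with a ``planted`` flag.
    """
    rng = _sub_rng(spec.seed, 1, stream)
    lengths = np.maximum(
        rng.lognormal(spec.length_mu, spec.length_sigma, size=spec.proteome_size).astype(int),
        spec.min_length,
    )
    proteome: dict[str, str] = {}
    truth_rows = []
    width = len(str(spec.proteome_size))
    for i, length in enumerate(lengths):
        pid = f"{prefix}{i:0{width}d}"
        plants = []
        for strength, rate in sorted(spec.plant_per_protein.items()):
            plants.extend([strength] * rng.poisson(rate))
        seq, planted = generate_sequence(rng, int(length), spec.aa_freqs, plants)
        proteome[pid] = seq
        planted_starts = {m.start for m in planted}
        for m in scan_motifs(seq, pid):
            cls = classify_motif(m, rules)
            truth_rows.append(
                {
                    "protein_id": pid,
                    "start": m.start,
                    "n": m.n,
                    "strength": cls.label if isinstance(cls, StrengthClass) else cls,
                    "planted": m.start in planted_starts,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "start", "n", "strength", "planted"])
    return proteome, truth


def plant_in_windows(
    proteome: dict[str, str],
    windows: Sequence[tuple[str, int, int]],
    strength: StrengthClass,
    probability: float,
    seed: int,
    stream: int = 0,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Plant one motif (w.p. ``probability``) into each listed window.

    Windows are (protein_id, lo, hi), 1-based positions allowed for the
    first proline.  Returns the updated proteome and (protein_id, start)
    of every planted motif.
    """
    rng = _sub_rng(seed, 7, stream)
    out = dict(proteome)
    planted: list[tuple[str, int]] = []
    freqs = ECOLI_AA_FREQS
    for pid, lo, hi in windows:
        if rng.random() >= probability:
            continue
        seq = out[pid]
        up, n, _ = _PLANT_CONTEXT[strength]
        lo_eff = max(lo, len(up) + 1)
        hi_eff = min(hi, len(seq) - n - 1)
        if hi_eff < lo_eff:
            continue
        pos0 = int(rng.integers(lo_eff - 1, hi_eff))
        arr = np.frombuffer(seq.encode("ascii"), np.uint8).copy()
        m = _plant_at(arr, pos0, strength, rng, freqs)
        out[pid] = arr.tobytes().decode("ascii")
        planted.append((pid, m.start))
    return out, planted


def thin_motifs(
    proteome: dict[str, str], fraction: float, seed: int, stream: int = 0
) -> dict[str, str]:
    """Break up a random fraction of proline stretches, preserving
    composition.

    Each maximal >=2P run is, with probability ``fraction``, dismantled by
    relocating its prolines to isolated positions (no proline neighbours)
    elsewhere in the same sequence.  The letter multiset — and hence the
    shuffle-null expectation — is unchanged, so the expected fold change
    against the null is ~(1 - fraction): the planted-depletion device.
    """
    rng = _sub_rng(seed, 11, stream)
    p_code = ord("P")
    out = {}
    for pid, seq in sorted(proteome.items()):
        arr = np.frombuffer(seq.encode("ascii"), np.uint8).copy()
        for m in scan_motifs(seq, pid):
            if rng.random() >= fraction:
                continue
            for i in range(m.start - 1, m.start - 1 + m.n):
                for _ in range(200):
                    j = int(rng.integers(0, len(arr)))
                    if arr[j] == p_code:
                        continue
                    lo, hi = max(j - 1, 0), min(j + 2, len(arr))
                    neighbours = [k for k in range(lo, hi) if k not in (j, i)]
                    if any(arr[k] == p_code for k in neighbours):
                        continue
                    if abs(j - i) == 1:
                        continue
                    arr[i], arr[j] = arr[j], p_code
                    break
        out[pid] = arr.tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Pan-genome


def generate_pangenome(
    spec: SyntheticSpec,
    rules: StrengthRuleTable,
    core_plant: dict[StrengthClass, float] | None = None,
    accessory_plant: dict[StrengthClass, float] | None = None,
) -> dict:
    """Per-strain proteomes + orthology table + ground-truth core labels.

    Core groups have one member in every strain; accessory groups in a
    random subset (each further strain included with the sharing rate); a
    small fraction of proteins is left unassigned (hence accessory).
    Differential motif planting between core and accessory groups supports
    occurrence-comparison tests.
    """
    if spec.n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = _sub_rng(spec.seed, 2)
    strains = [f"S{i:02d}" for i in range(spec.n_strains)]
    n_groups = max(int(round(spec.proteome_size * (1 - spec.unassigned_fraction))), 1)
    n_core = int(round(n_groups * spec.core_fraction))

    proteomes: dict[str, dict[str, str]] = {s: {} for s in strains}
    og_rows = []
    truth_labels: dict[str, str] = {}
    truth_rows = []
    counter = 0

    def make_protein(strain: str, plant: dict[StrengthClass, float], group_core: bool):
        nonlocal counter
        pid = f"{strain}_p{counter:06d}"
        counter += 1
        length = max(int(rng.lognormal(spec.length_mu, spec.length_sigma)), spec.min_length)
        plants = []
        for strength, rate in sorted((plant or {}).items()):
            plants.extend([strength] * rng.poisson(rate))
        seq, _ = generate_sequence(rng, length, spec.aa_freqs, plants)
        proteomes[strain][pid] = seq
        for m in scan_motifs(seq, pid):
            cls = classify_motif(m, rules)
            truth_rows.append({"protein_id": pid, "start": m.start, "n": m.n,
                               "strength": cls.label if isinstance(cls, StrengthClass) else cls})
        return pid

    for g in range(n_groups):
        og_id = f"OG{g:05d}"
        is_core = g < n_core
        if is_core:
            members = strains
        else:
            k = 1 + int(rng.binomial(spec.n_strains - 1, spec.accessory_sharing_rate))
            members = sorted(rng.choice(strains, size=min(k, spec.n_strains), replace=False))
        actually_core = set(members) == set(strains)
        plant = core_plant if actually_core else accessory_plant
        for strain in members:
            pid = make_protein(strain, plant or {}, actually_core)
            og_rows.append({"og_id": og_id, "strain": strain, "protein_id": pid})
            truth_labels[pid] = "CORE" if actually_core else "ACCESSORY"

    n_unassigned = max(int(round(spec.proteome_size * spec.unassigned_fraction)), 0)
    for strain in strains:
        for _ in range(n_unassigned // spec.n_strains):
            pid = make_protein(strain, accessory_plant or {}, False)
            truth_labels[pid] = "ACCESSORY"

    return {
        "proteomes": proteomes,
        "og_table": pd.DataFrame(og_rows, columns=["og_id", "strain", "protein_id"]),
        "true_labels": pd.Series(truth_labels, name="label").sort_index(),
        "motif_truth": pd.DataFrame(truth_rows, columns=["protein_id", "start", "n", "strength"]),
    }


# ---------------------------------------------------------------------------
# Trees and state histories


def _rate_matrix(alpha: float, gain_bias: float) -> np.ndarray:
    """CTMC rates on the 4 stalling states: downward moves at rate alpha,
    upward at alpha * gain_bias; gain_bias = 1 is the symmetric process."""
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = alpha * (gain_bias if j > i else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _evolve_branch(state: int, t: float, q: np.ndarray, rng: np.random.Generator) -> int:
    """Simulate the jump process for time t from the given state."""
    now = 0.0
    while True:
        rate = -q[state, state]
        if rate <= 0:
            return state
        now += rng.exponential(1.0 / rate)
        if now >= t:
            return state
        probs = q[state].clip(min=0)
        probs = probs / probs.sum()
        state = int(rng.choice(4, p=probs))


def simulate_state_evolution(spec: SyntheticSpec, stream: int = 0) -> dict:
    """Yule tree + stalling states evolved from the root.

    Returns the rooted tree (dendropy), leaf states, true states of every
    node, and the list of branches whose endpoint states differ (with
    direction), i.e. the ground-truth gain/loss events.
    """
    if spec.n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    seed_int = int(_sub_rng(spec.seed, 3, stream).integers(0, 2**31 - 1))
    taxa = dendropy.TaxonNamespace([f"L{i:03d}" for i in range(spec.n_leaves)])
    tree = treesim.birth_death_tree(
        birth_rate=spec.birth_rate,
        death_rate=0.0,
        num_extant_tips=spec.n_leaves,
        taxon_namespace=taxa,
        rng=random.Random(seed_int),
    )
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= spec.branch_scale

    rng = _sub_rng(spec.seed, 4, stream)
    q = _rate_matrix(spec.state_rate, spec.gain_bias)
    probs = np.asarray(spec.root_state_probs, dtype=float)
    probs = probs / probs.sum()
    node_states: dict[int, int] = {}
    events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_states[id(node)] = int(rng.choice(4, p=probs))
            continue
        parent_state = node_states[id(node.parent_node)]
        child_state = _evolve_branch(parent_state, node.edge.length or 0.0, q, rng)
        node_states[id(node)] = child_state
        if child_state > parent_state:
            events.append((node, "GAIN"))
        elif child_state < parent_state:
            events.append((node, "LOSS"))

    leaf_states = {
        leaf.taxon.label: StrengthClass(node_states[id(leaf)])
        for leaf in tree.leaf_node_iter()
    }
    return {
        "tree": tree,
        "leaf_states": leaf_states,
        "true_states": {k: StrengthClass(v) for k, v in node_states.items()},
        "true_events": events,
    }


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    spec: SyntheticSpec,
    proteome: Mapping[str, str],
    domains_per_protein: int = 2,
    tmh_fraction: float = 0.2,
    stream: int = 0,
) -> dict:
    """Domain and TMH annotation tracks for a proteome.

    Domains: ``domains_per_protein`` non-overlapping intervals per protein
    long enough to hold them.  TMHs: a fraction of proteins become
    transmembrane, with helix lengths centred on 21 residues and >=15
    residue spacing.
    """
    from .positional import DOMAIN, TMH, AnnotationTrack

    rng = _sub_rng(spec.seed, 5, stream)
    domain_ivs: dict[str, list[tuple[int, int]]] = {}
    tmh_ivs: dict[str, list[tuple[int, int]]] = {}
    for pid, seq in sorted(proteome.items()):
        length = len(seq)
        if length >= 100 * domains_per_protein:
            ivs = []
            cursor = 1 + int(rng.integers(5, 15))
            for _ in range(domains_per_protein):
                dlen = int(rng.integers(60, 90))
                if cursor + dlen - 1 > length:
                    break
                ivs.append((cursor, cursor + dlen - 1))
                cursor += dlen + int(rng.integers(8, 25))
            if len(ivs) >= 1:
                domain_ivs[pid] = ivs
        if rng.random() < tmh_fraction and length >= 120:
            ivs = []
            cursor = 1 + int(rng.integers(10, 30))
            while True:
                tlen = int(np.clip(round(rng.normal(21, 1.5)), 17, 25))
                if cursor + tlen - 1 > length:
                    break
                ivs.append((cursor, cursor + tlen - 1))
                cursor += tlen + int(rng.integers(15, 60))
            if ivs:
                tmh_ivs[pid] = ivs
    return {
        "domains": AnnotationTrack(kind=DOMAIN, intervals=domain_ivs).validate(proteome),
        "tmh": AnnotationTrack(kind=TMH, intervals=tmh_ivs).validate(proteome),
    }


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    spec: SyntheticSpec,
    densities: Mapping[str, float],
    max_strength: Mapping[str, StrengthClass] | None = None,
    stream: int = 0,
) -> dict:
    """Expression table with a target Spearman correlation to motif density,
    plus ribosome-profiling asymmetry scores associated with motif strength.

    A Gaussian copula links translation efficiency to the density ranks:
    the normal scores of the densities are mixed with independent noise at
    the Pearson equivalent of the target Spearman rho.
    """
    rng = _sub_rng(spec.seed, 6, stream)
    genes = sorted(densities)
    n = len(genes)
    d = np.array([densities[g] for g in genes], dtype=float)
    d_jittered = d + rng.normal(0, 1e-9, n)  # break ties uniformly
    ranks = rankdata(d_jittered)
    z_d = norm.ppf((ranks - 0.5) / n)
    rho_pearson = 2.0 * np.sin(np.pi * spec.target_rho / 6.0)
    z_te = rho_pearson * z_d + np.sqrt(max(1 - rho_pearson**2, 0.0)) * rng.normal(size=n)
    log_te = 1.5 + 0.5 * z_te * spec.expression_noise
    te = 10.0 ** log_te
    transcription = 10.0 ** rng.normal(2.0, 0.4, size=n)
    abundance = te * transcription

    expression = pd.DataFrame(
        {
            "gene_id": genes,
            "protein_abundance": abundance,
            "transcription_level": transcription,
        }
    )
    scores = {}
    for i, g in enumerate(genes):
        strong = max_strength is not None and max_strength.get(g, StrengthClass.NONE) >= StrengthClass.MEDIUM
        mu = 1.2 if strong else 0.0
        scores[g] = float(10.0 ** rng.normal(mu * 0.3, 0.25))
    return {"expression": expression, "stall_scores": scores}
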