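"""Evolution of ribosome-stalling states across orthologous groups.

Motif-bearing alignment regions are extracted from per-group multiple
sequence alignments; each leaf of the group's phylogenetic tree is assigned
one of four stalling states — N (none) < W (weak) < M (medium) < S (strong)
— from the strongest motif overlapping the region in that sequence.
Ancestral states are reconstructed by maximum likelihood under a symmetric
4-state Markov (Mk) model on the midpoint-rooted tree; branches on which the
state rank increases are gain events, decreases are losses.  The propensity
of stalling-effect change,

    PSEC = sum(B_g)/sum(B_cg) - sum(B_l)/sum(B_cl),

contrasts the branch-length fraction carrying gains (among branches where a
gain was possible, parent not already S) with the fraction carrying losses
(parent not N).  Negative PSEC means the stalling effect tends to be lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .motifs import StrengthClass

#: State order used everywhere: index == rank.
STATES = [StrengthClass.NONE, StrengthClass.WEAK, StrengthClass.MEDIUM, StrengthClass.STRONG]
STATE_LABELS = ["N", "W", "M", "S"]
N_STATES = 4

GAIN = "GAIN"
LOSS = "LOSS"


# ---------------------------------------------------------------------------
# Aligned regions


@dataclass
class AlignedRegion:
    """A merged alignment-column interval containing >=1 motif.

    ``columns`` is (start, end), 1-based inclusive; ``leaf_states`` maps each
    aligned sequence id to the strength of its strongest motif overlapping
    the region (NONE when it has none).  ``fragmented`` flags regions where a
    proline stretch is split by gap columns.
    """

    og_id: str
    columns: tuple[int, int]
    leaf_states: dict[str, StrengthClass]
    fragmented: bool = False


def _residue_to_column(aligned: str) -> np.ndarray:
    """1-based residue position -> 1-based alignment column."""
    cols = np.flatnonzero(np.frombuffer(aligned.encode("ascii"), np.uint8) != ord("-")) + 1
    return cols


def map_motifs_to_alignment(
    msa: Mapping[str, str],
    motif_table: pd.DataFrame,
    og_id: str = "",
    proteome: Mapping[str, str] | None = None,
) -> list[AlignedRegion]:
    """Project motif proline stretches onto alignment columns and merge
    overlapping intervals across sequences into regions.

    ``motif_table`` must carry rows for the sequences of this alignment
    (columns protein_id, start, n, strength).  If ``proteome`` is given,
    each de-gapped aligned sequence is checked against it.
    """
    width = {len(a) for a in msa.values()}
    if len(width) != 1:
        raise ValueError("alignment rows have unequal lengths")
    res2col = {}
    for sid, aligned in msa.items():
        if proteome is not None and sid in proteome:
            degapped = aligned.replace("-", "")
            if degapped != proteome[sid]:
                raise ValueError(f"de-gapped alignment row does not match proteome sequence: {sid}")
        res2col[sid] = _residue_to_column(aligned)

    # column interval of each motif's proline stretch
    intervals: list[tuple[int, int, str, StrengthClass | None, bool]] = []
    sub = motif_table[motif_table["protein_id"].isin(msa.keys())]
    for row in sub.itertuples():
        cols = res2col[row.protein_id]
        if row.start + row.n - 1 > len(cols):
            raise ValueError(f"motif beyond sequence end for {row.protein_id}")
        span = cols[row.start - 1 : row.start + row.n - 1]
        fragmented = bool(span[-1] - span[0] + 1 != len(span))
        strength = (
            StrengthClass[row.strength]
            if row.strength in StrengthClass.__members__
            else None  # AMBIGUOUS: contributes columns but no state
        )
        intervals.append((int(span[0]), int(span[-1]), row.protein_id, strength, fragmented))
    if not intervals:
        return []

    # transitive merge of overlapping column intervals
    intervals.sort(key=lambda t: (t[0], t[1]))
    merged: list[list] = []
    for iv in intervals:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv[1])
            merged[-1][2].append(iv)
        else:
            merged.append([iv[0], iv[1], [iv]])

    regions = []
    for start, end, ivs in merged:
        states = {sid: StrengthClass.NONE for sid in msa}
        for _, _, sid, strength, _ in ivs:
            if strength is not None and strength > states[sid]:
                states[sid] = strength
        regions.append(
            AlignedRegion(
                og_id=og_id,
                columns=(start, end),
                leaf_states=states,
                fragmented=any(iv[4] for iv in ivs),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Midpoint rooting


def _leaf_paths(tree: dendropy.Tree) -> dict:
    """Chain of (node, cumulative distance) from each leaf up to the seed node."""
    chains = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node, dist = leaf, 0.0
        while node is not None:
            chain.append((node, dist))
            if node.edge.length:
                dist += node.edge.length
            node = node.parent_node
        chains[leaf.taxon.label] = chain
    return chains


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path.

    Pairwise path lengths are preserved; ties on the diameter are broken
    toward the lexicographically smallest (leaf, leaf) label pair.  A tree
    whose branch lengths are all zero is rooted at the seed node and the
    tree annotated with ``midpoint_degenerate=True``.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    chains = _leaf_paths(tree)
    labels = sorted(chains)
    if len(labels) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")

    best = None  # (distance, (label_a, label_b))
    index = {lab: {id(n): d for n, d in chain} for lab, chain in chains.items()}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            # splice at the deepest shared node of the two root chains
            shared = [(n, da) for n, da in chains[a] if id(n) in index[b]]
            lca, d_lca_a = shared[0]
            dist = d_lca_a + index[b][id(lca)]
            if best is None or dist > best[0] + 1e-15:
                best = (dist, (a, b))
    diameter, (a, b) = best
    if diameter <= 0:
        tree.midpoint_degenerate = True
        return tree
    tree.midpoint_degenerate = False

    # ordered node path a -> b
    chain_a, chain_b = chains[a], chains[b]
    shared_ids = {id(n) for n, _ in chain_a} & {id(n) for n, _ in chain_b}
    up = [(n, d) for n, d in chain_a if id(n) not in shared_ids]
    lca_node, d_lca = next((n, d) for n, d in chain_a if id(n) in shared_ids)
    d_b_lca = index[b][id(lca_node)]
    down = [
        (n, d_lca + (d_b_lca - db))
        for n, db in reversed(chain_b)
        if id(n) not in shared_ids
    ]
    path = [*up, (lca_node, d_lca), *down]  # (node, cumulative distance from a)

    target = diameter / 2.0
    for (n1, d1), (n2, d2) in zip(path, path[1:]):
        if d2 >= target - 1e-12:
            # midpoint lies on the edge between n1 and n2
            child = n2 if n2.parent_node is n1 else n1  # edge stored on the child
            if abs(d2 - target) <= 1e-12 and not n2.is_leaf():
                tree.reroot_at_node(n2, update_bipartitions=False)
            elif abs(d1 - target) <= 1e-12 and not n1.is_leaf():
                tree.reroot_at_node(n1, update_bipartitions=False)
            else:
                edge = child.edge
                # segment adjacent to the edge's head (child) end
                length_head = (d2 - target) if child is n2 else (target - d1)
                tree.reroot_at_edge(
                    edge,
                    length1=edge.length - length_head,
                    length2=length_head,
                    update_bipartitions=False,
                )
            break
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# Ancestral state reconstruction (symmetric 4-state Mk)


def transition_matrix(alpha: float, t: float) -> np.ndarray:
    """P(t) for the symmetric 4-state model: off-diagonal rate alpha.

    p_same(t) = 1/4 + 3/4 exp(-4 alpha t); p_diff(t) = 1/4 - 1/4 exp(-4 alpha t).
    """
    e = np.exp(-4.0 * alpha * t)
    p_diff = 0.25 - 0.25 * e
    mat = np.full((N_STATES, N_STATES), p_diff)
    np.fill_diagonal(mat, 0.25 + 0.75 * e)
    return mat


@dataclass
class StateTree:
    """Rooted tree with observed leaf and reconstructed internal states."""

    tree: dendropy.Tree
    alpha: float
    log_likelihood: float
    node_states: dict[int, StrengthClass] = field(default_factory=dict)  # id(node) -> state

    def state_of(self, node) -> StrengthClass:
        return self.node_states[id(node)]


def _postorder_likelihoods(tree, leaf_states, alpha):
    """Conditional (pruning) likelihoods for every node; returns dict id->vec."""
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(N_STATES)
            vec[int(leaf_states[node.taxon.label])] = 1.0
            down[id(node)] = vec
        else:
            vec = np.ones(N_STATES)
            for child in node.child_nodes():
                pmat = transition_matrix(alpha, child.edge.length or 0.0)
                vec = vec * (pmat @ down[id(child)])
            down[id(node)] = vec
    return down


def mk_log_likelihood(tree: dendropy.Tree, leaf_states: Mapping[str, StrengthClass], alpha: float) -> float:
    """Pruning-algorithm log-likelihood under a uniform root prior."""
    down = _postorder_likelihoods(tree, leaf_states, alpha)
    lik = float(np.sum(down[id(tree.seed_node)]) / N_STATES)
    return np.log(lik) if lik > 0 else -np.inf


def reconstruct_ancestral_states(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, StrengthClass],
    alpha: float | None = None,
    alpha_bounds: tuple[float, float] = (1e-6, 100.0),
) -> StateTree:
    """Maximum-likelihood marginal ancestral states on a rooted tree.

    The single Mk rate ``alpha`` is optimised by bounded 1-D likelihood
    maximisation unless supplied.  Each node receives the state of maximal
    marginal posterior (uniform root prior); posterior ties break toward the
    weaker state, conservative against inferring gains.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = leaves - set(leaf_states)
    if missing:
        raise ValueError(f"leaf states missing for: {sorted(missing)[:5]}")

    if alpha is None:
        # the likelihood flattens for large alpha (all transition matrices
        # -> uniform), so a bounded search alone can stall on the plateau;
        # a log-spaced grid scan brackets the optimum first
        grid = np.geomspace(alpha_bounds[0], alpha_bounds[1], 25)
        values = [mk_log_likelihood(tree, leaf_states, a) for a in grid]
        k = int(np.argmax(values))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda a: -mk_log_likelihood(tree, leaf_states, a),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        alpha = float(res.x)

    down = _postorder_likelihoods(tree, leaf_states, alpha)
    loglik = mk_log_likelihood(tree, leaf_states, alpha)

    # upward ("outside") pass: up[v][s] is the likelihood of everything
    # outside the clade of v, given state s at v
    up: dict[int, np.ndarray] = {id(tree.seed_node): np.full(N_STATES, 1.0 / N_STATES)}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            sib_prod = np.ones(N_STATES)
            for sib in children:
                if sib is not child:
                    pmat = transition_matrix(alpha, sib.edge.length or 0.0)
                    sib_prod *= pmat @ down[id(sib)]
            pmat = transition_matrix(alpha, child.edge.length or 0.0)
            up[id(child)] = (up[id(node)] * sib_prod) @ pmat

    node_states: dict[int, StrengthClass] = {}
    posteriors: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        post = up[id(node)] * down[id(node)]
        total = post.sum()
        post = post / total if total > 0 else np.full(N_STATES, 0.25)
        posteriors[id(node)] = post
        if node.is_leaf():
            node_states[id(node)] = leaf_states[node.taxon.label]
        else:
            # argmax returns the first (weakest) index among exact ties
            best = np.flatnonzero(post >= post.max() - 1e-12)[0]
            node_states[id(node)] = STATES[int(best)]

    st = StateTree(tree=tree, alpha=alpha, log_likelihood=loglik, node_states=node_states)
    st.posteriors = posteriors
    return st


def marginal_posteriors(state_tree: StateTree) -> dict[int, np.ndarray]:
    return state_tree.posteriors


# ---------------------------------------------------------------------------
# Events and PSEC


def count_events(state_tree: StateTree) -> list[tuple[object, str]]:
    """(branch child node, GAIN|LOSS) for every branch whose endpoint states
    differ; rank(child) > rank(parent) is a gain, lower is a loss."""
    events = []
    for node in state_tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        ps, cs = state_tree.state_of(parent), state_tree.state_of(node)
        if cs > ps:
            events.append((node, GAIN))
        elif cs < ps:
            events.append((node, LOSS))
    return events


@dataclass
class PSECResult:
    b_g: float
    b_l: float
    b_cg: float
    b_cl: float
    gains: int
    losses: int
    psec: float


def compute_psec(state_tree: StateTree, events: list[tuple[object, str]]) -> PSECResult:
    """PSEC = B_g/B_cg - B_l/B_cl over the reconstructed tree.

    A branch admits a gain iff its parent is not already at the maximal
    state S, and a loss iff its parent is not N; a ratio with zero
    denominator contributes 0.
    """
    event_by_node = {id(node): kind for node, kind in events}
    b_g = b_l = b_cg = b_cl = 0.0
    gains = losses = 0
    for node in state_tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        length = node.edge.length or 0.0
        ps = state_tree.state_of(parent)
        if ps < StrengthClass.STRONG:
            b_cg += length
        if ps > StrengthClass.NONE:
            b_cl += length
        kind = event_by_node.get(id(node))
        if kind == GAIN:
            b_g += length
            gains += 1
        elif kind == LOSS:
            b_l += length
            losses += 1
    term_g = b_g / b_cg if b_cg > 0 else 0.0
    term_l = b_l / b_cl if b_cl > 0 else 0.0
    return PSECResult(b_g=b_g, b_l=b_l, b_cg=b_cg, b_cl=b_cl, gains=gains, losses=losses,
                      psec=term_g - term_l)


def psec_cohort_summary(psec_values: Sequence[float]) -> dict:
    """Counts/fractions of regions with PSEC >0 / <0 / =0 and a chi-squared
    test of the 50:50 split among the nonzero-PSEC regions."""
    vals = np.asarray(list(psec_values), dtype=float)
    n_pos = int(np.sum(vals > 0))
    n_neg = int(np.sum(vals < 0))
    n_zero = int(np.sum(vals == 0))
    n_nonzero = n_pos + n_neg
    if n_nonzero > 0:
        chi = stats.chisquare([n_pos, n_neg])
        p = float(chi.pvalue)
        frac_pos = n_pos / n_nonzero
        frac_neg = n_neg / n_nonzero
    else:
        p, frac_pos, frac_neg = float("nan"), float("nan"), float("nan")
    return {
        "n_regions": len(vals),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "n_zero": n_zero,
        "frac_positive_nonzero": frac_pos,
        "frac_negative_nonzero": frac_neg,
        "chi2_p": p,
    }
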