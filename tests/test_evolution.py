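"""Region extraction, rooting, ancestral reconstruction, events and PSEC."""

import itertools
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.simulate import treesim

from polypro.evolution import (
    GAIN,
    LOSS,
    STATES,
    StateTree,
    compute_psec,
    count_events,
    map_motifs_to_alignment,
    midpoint_root,
    mk_log_likelihood,
    psec_cohort_summary,
    reconstruct_ancestral_states,
    transition_matrix,
)
from polypro.motifs import StrengthClass


def yule_tree(n_leaves, seed, scale=1.0):
    taxa = dendropy.TaxonNamespace([f"L{i:03d}" for i in range(n_leaves)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=taxa, rng=random.Random(seed),
    )
    tree.is_rooted = True
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            # clamp: zero-length branches make conflicting leaf states
            # impossible (zero likelihood), degenerate for oracle comparison
            e.length = max(e.length * scale, 0.01)
    return tree


def brute_force_posteriors(tree, leaf_states, alpha):
    """Exhaustive summation over all joint internal-state assignments."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    post = {id(n): np.zeros(4) for n in internal}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        for n in nodes:
            if n.is_leaf():
                amap[id(n)] = int(leaf_states[n.taxon.label])
        lik = 0.25
        for n in nodes:
            if n.parent_node is not None:
                pmat = transition_matrix(alpha, n.edge.length or 0.0)
                lik *= pmat[amap[id(n.parent_node)], amap[id(n)]]
        total += lik
        for n in internal:
            post[id(n)][amap[id(n)]] += lik
    return {k: v / total for k, v in post.items()}, np.log(total)


def leaf_depths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        d, n = 0.0, leaf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[leaf.taxon.label] = d
    return out


def pairwise_leaf_distances(tree):
    m = tree.clone(depth=1).phylogenetic_distance_matrix()
    taxa = sorted(m.taxon_iter(), key=lambda t: t.label)
    return {(a.label, b.label): m.distance(a, b) for a, b in itertools.combinations(taxa, 2)}


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        tree = dendropy.Tree.get(data="(A:2,B:4);", schema="newick")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        assert depths["A"] == pytest.approx(3.0)
        assert depths["B"] == pytest.approx(3.0)

    def test_root_on_longest_path(self):
        tree = dendropy.Tree.get(data="((A:4,C:1):1,B:5);", schema="newick")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        # A-B path is longest (10); root 5 from each
        assert depths["A"] == pytest.approx(5.0)
        assert depths["B"] == pytest.approx(5.0)

    def test_random_trees_balanced_and_distance_preserving(self):
        for seed in range(15):
            tree = yule_tree(20, seed)
            before = pairwise_leaf_distances(tree)
            rooted = midpoint_root(tree)
            after = pairwise_leaf_distances(rooted)
            for k, v in before.items():
                assert after[k] == pytest.approx(v, abs=1e-9)
            depths = sorted(leaf_depths(rooted).values())
            assert depths[-1] - depths[-2] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_lengths_flagged(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,C:0);", schema="newick")
        rooted = midpoint_root(tree)
        assert rooted.midpoint_degenerate


class TestMapMotifsToAlignment:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "start", "n", "strength"])

    def test_identical_sequences_one_region(self):
        msa = {"s1": "MAPPG", "s2": "MAPPG", "s3": "MAPPG"}
        table = self.make_table([(s, 3, 2, "STRONG") for s in msa])
        regions = map_motifs_to_alignment(msa, table, og_id="og1")
        assert len(regions) == 1
        region = regions[0]
        assert region.columns == (3, 4)
        assert all(v == StrengthClass.STRONG for v in region.leaf_states.values())

    def test_absent_motif_gives_none_state(self):
        msa = {"s1": "MAPPG", "s2": "MAKLG", "s3": "MAKLG"}
        table = self.make_table([("s1", 3, 2, "MEDIUM")])
        (region,) = map_motifs_to_alignment(msa, table)
        assert region.leaf_states == {
            "s1": StrengthClass.MEDIUM,
            "s2": StrengthClass.NONE,
            "s3": StrengthClass.NONE,
        }

    def test_gapped_coordinates_round_trip(self, rng):
        # random gap insertion: region column span must map back exactly
        from polypro.motifs import scan_motifs

        base = "MAKPPGLLVKPPPA"
        for trial in range(30):
            gapped = []
            for ch in base:
                while rng.random() < 0.25:
                    gapped.append("-")
                gapped.append(ch)
            aligned = "".join(gapped)
            msa = {"s1": aligned, "s2": "-" * len(aligned)}
            msa["s2"] = aligned  # two identical rows keep the region shared
            motifs = scan_motifs(base, "s1")
            table = self.make_table(
                [("s1", m.start, m.n, "WEAK") for m in motifs]
                + [("s2", m.start, m.n, "WEAK") for m in motifs]
            )
            regions = map_motifs_to_alignment(msa, table)
            assert len(regions) == len(motifs)
            # independent gap bookkeeping: residue index of each column
            col_to_res = np.cumsum([c != "-" for c in aligned])
            for region, motif in zip(regions, motifs):
                lo, hi = region.columns
                assert col_to_res[lo - 1] == motif.start
                assert col_to_res[hi - 1] == motif.start + motif.n - 1

    def test_overlapping_intervals_merge(self):
        msa = {"s1": "APPPA", "s2": "AAPPP"}
        table = self.make_table([("s1", 2, 3, "STRONG"), ("s2", 3, 3, "STRONG")])
        regions = map_motifs_to_alignment(msa, table)
        assert len(regions) == 1
        assert regions[0].columns == (2, 5)

    def test_proteome_mismatch_rejected(self):
        msa = {"s1": "MA-PP"}
        table = self.make_table([("s1", 4, 2, "WEAK")])
        with pytest.raises(ValueError, match="s1"):
            map_motifs_to_alignment(msa, table, proteome={"s1": "MAXPP"})


class TestReconstruction:
    def test_uniform_leaves_stay_uniform(self):
        tree = yule_tree(6, 3)
        states = {leaf.taxon.label: StrengthClass.STRONG for leaf in tree.leaf_node_iter()}
        st = reconstruct_ancestral_states(tree, states)
        assert all(s == StrengthClass.STRONG for s in st.node_states.values())

    def test_three_leaf_star_majority(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        tree.is_rooted = True
        st = reconstruct_ancestral_states(
            tree,
            {"A": StrengthClass.STRONG, "B": StrengthClass.STRONG, "C": StrengthClass.NONE},
            alpha=0.3,
        )
        # direct summation over the 4 root states: S maximises
        # P(root) * p(root->S)^2 * p(root->N)
        pmat = transition_matrix(0.3, 1.0)
        scores = [pmat[s, 3] ** 2 * pmat[s, 0] for s in range(4)]
        assert int(np.argmax(scores)) == 3
        assert st.state_of(tree.seed_node) == StrengthClass.STRONG

    def test_matches_brute_force_enumeration(self):
        for seed in range(8):
            tree = yule_tree(5, 40 + seed)
            rng = np.random.default_rng(seed)
            states = {f"L{i:03d}": STATES[rng.integers(0, 4)] for i in range(5)}
            alpha = float(rng.uniform(0.1, 2.0))
            st = reconstruct_ancestral_states(tree, states, alpha=alpha)
            oracle_post, oracle_loglik = brute_force_posteriors(tree, states, alpha)
            assert st.log_likelihood == pytest.approx(oracle_loglik, abs=1e-9)
            for node in tree.postorder_node_iter():
                if not node.is_leaf():
                    np.testing.assert_allclose(
                        st.posteriors[id(node)], oracle_post[id(node)], atol=1e-9
                    )

    def test_missing_leaf_state_rejected(self):
        tree = yule_tree(4, 0)
        with pytest.raises(ValueError, match="L003"):
            reconstruct_ancestral_states(tree, {f"L{i:03d}": StrengthClass.NONE for i in range(3)})

    def test_alpha_optimised_when_not_given(self):
        tree = yule_tree(8, 5)
        rng = np.random.default_rng(2)
        states = {f"L{i:03d}": STATES[rng.integers(0, 4)] for i in range(8)}
        st = reconstruct_ancestral_states(tree, states)
        for alpha in [st.alpha * 0.5, min(st.alpha * 2, 100.0)]:
            # alternatives inside the optimisation bounds never beat the MLE
            assert mk_log_likelihood(tree, states, alpha) <= st.log_likelihood + 1e-6


class TestEventsAndPsec:
    def _state_tree(self, newick, states):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        node_states = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node_states[id(node)] = states[node.taxon.label]
            else:
                node_states[id(node)] = states.get("__root__", StrengthClass.NONE)
        return StateTree(tree=tree, alpha=1.0, log_likelihood=0.0, node_states=node_states)

    def test_gain_and_loss_direction(self):
        st = self._state_tree(
            "(A:1,B:1);",
            {"A": StrengthClass.STRONG, "B": StrengthClass.NONE, "__root__": StrengthClass.WEAK},
        )
        events = dict(
            (node.taxon.label, kind) for node, kind in count_events(st)
        )
        assert events == {"A": GAIN, "B": LOSS}

    def test_no_events_on_constant_tree(self):
        st = self._state_tree(
            "(A:1,B:1);",
            {"A": StrengthClass.WEAK, "B": StrengthClass.WEAK, "__root__": StrengthClass.WEAK},
        )
        assert count_events(st) == []
        res = compute_psec(st, [])
        assert res.psec == 0.0

    def test_events_equal_changed_branches(self):
        for seed in range(20):
            from polypro.simulate import SyntheticSpec, simulate_state_evolution

            sim = simulate_state_evolution(SyntheticSpec(seed=seed, n_leaves=8, state_rate=1.5))
            st = StateTree(
                tree=sim["tree"], alpha=1.0, log_likelihood=0.0,
                node_states={k: v for k, v in sim["true_states"].items()},
            )
            events = count_events(st)
            changed = sum(
                1
                for node in sim["tree"].preorder_node_iter()
                if node.parent_node is not None
                and sim["true_states"][id(node)] != sim["true_states"][id(node.parent_node)]
            )
            assert len(events) == changed

    def test_single_gain_value(self):
        # one gain on a branch of length 1 with total gain-possible length 6
        tree = dendropy.Tree.get(data="((A:1,B:2):3,C:1);", schema="newick")
        tree.is_rooted = True
        nodes = {n.taxon.label: n for n in tree.leaf_node_iter()}
        inner = nodes["A"].parent_node
        root = tree.seed_node
        node_states = {
            id(root): StrengthClass.NONE,
            id(inner): StrengthClass.NONE,
            id(nodes["A"]): StrengthClass.MEDIUM,
            id(nodes["B"]): StrengthClass.NONE,
            id(nodes["C"]): StrengthClass.NONE,
        }
        st = StateTree(tree=tree, alpha=1.0, log_likelihood=0.0, node_states=node_states)
        events = count_events(st)
        assert [kind for _, kind in events] == [GAIN]
        res = compute_psec(st, events)
        assert res.b_cg == pytest.approx(7.0)  # all branches admit a gain
        assert res.b_cl == pytest.approx(0.0)  # nothing to lose anywhere
        assert res.psec == pytest.approx(1.0 / 7.0)

    def test_psec_bounds_random(self):
        from polypro.simulate import SyntheticSpec, simulate_state_evolution

        for seed in range(30):
            sim = simulate_state_evolution(SyntheticSpec(seed=seed, n_leaves=6, state_rate=2.0))
            st = StateTree(tree=sim["tree"], alpha=1.0, log_likelihood=0.0,
                           node_states=dict(sim["true_states"]))
            res = compute_psec(st, count_events(st))
            assert -1.0 <= res.psec <= 1.0
            assert res.b_g <= res.b_cg + 1e-12
            assert res.b_l <= res.b_cl + 1e-12

    def test_loss_only_process_negative_psec(self):
        from polypro.simulate import SyntheticSpec, simulate_state_evolution

        vals = []
        for seed in range(100):
            sim = simulate_state_evolution(
                SyntheticSpec(seed=seed, n_leaves=16, state_rate=0.25, gain_bias=0.0,
                              root_state_probs=(0, 0, 0, 1))
            )
            st = reconstruct_ancestral_states(sim["tree"], sim["leaf_states"])
            res = compute_psec(st, count_events(st))
            vals.append(res.psec)
        vals = np.asarray(vals)
        assert np.median(vals) < 0
        nonzero = vals[vals != 0]
        assert (nonzero < 0).mean() >= 0.8

    def test_cohort_summary(self):
        summary = psec_cohort_summary([0.2, -0.1, -0.3, 0.0, -0.2])
        assert summary["n_positive"] == 1
        assert summary["n_negative"] == 3
        assert summary["n_zero"] == 1
        assert summary["frac_negative_nonzero"] == pytest.approx(0.75)
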