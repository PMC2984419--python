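"""Discrete parsimony scenarios and Brownian-motion ancestral states."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest

from codereassign.seqio import PhyloTree
from codereassign.synthetic_data import simulate_bm_on_tree, simulate_tree
from codereassign.trait_reconstruction import (
    bm_ancestral_ml,
    camin_sokal_parsimony,
    fitch_parsimony,
    renormalize_simplex,
)


def brute_force_min_changes(tree, tip_states, irreversible, root_state=None):
    """Exhaustive enumeration over all internal-node labelings."""
    internal = [n for n in tree.dtree.preorder_node_iter() if not n.is_leaf()]
    best = float("inf")
    best_count = 0
    for combo in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip(map(id, internal), combo))
        if root_state is not None and states[id(tree.root)] != root_state:
            continue
        cost = 0
        ok = True
        for node in tree.dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = tip_states[node.taxon.label] if node.is_leaf() else states[id(node)]
            p = states[id(node.parent_node)]
            if p != s:
                if irreversible and p == 1:
                    ok = False
                    break
                cost += 1
        if not ok:
            continue
        if cost < best:
            best, best_count = cost, 1
        elif cost == best:
            best_count += 1
    return best, best_count


class TestFitchParsimony:
    def test_all_tips_same_state(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rec = fitch_parsimony(tree, {t: 0 for t in "ABCD"})
        assert rec.min_changes == 0
        assert rec.n_gains == rec.n_losses == 0

    def test_two_tip_tree(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        rec = fitch_parsimony(tree, {"A": 0, "B": 1})
        assert rec.min_changes == 1

    def test_unlabeled_tip_errors(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            fitch_parsimony(tree, {"A": 0})

    def test_fig1_single_origin_plus_reversal(self, fig1):
        """The study topology admits a unique MP labeling: one gain on the
        five-lineage stem, one reversal on the Bryopsidales stem."""
        tree, states = fig1
        rec = fitch_parsimony(tree, states)
        assert rec.min_changes == 2
        assert rec.n_mp_labelings == 1
        events = dict((frozenset(c), e) for c, e in rec.event_edges)
        five = frozenset(
            ["Trentepohliales", "Dasycladales", "Bryopsidales", "Cladophorales", "Blastophysa"]
        )
        assert events == {five: "gain", frozenset(["Bryopsidales"]): "loss"}

    def test_gains_plus_losses_equal_min_changes(self, rng):
        for _ in range(20):
            tree = simulate_tree(int(rng.integers(4, 10)), rng=rng)
            states = {t: int(rng.integers(0, 2)) for t in tree.tip_labels}
            rec = fitch_parsimony(tree, states)
            for lab in rec.labelings:
                assert lab.n_changes == rec.min_changes

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            tree = simulate_tree(int(rng.integers(4, 13)), rng=rng)
            states = {t: int(rng.integers(0, 2)) for t in tree.tip_labels}
            rec = fitch_parsimony(tree, states)
            best, count = brute_force_min_changes(tree, states, False)
            assert rec.min_changes == best
            assert rec.n_mp_labelings == count

    def test_invariant_under_tip_permutation(self, rng):
        tree = simulate_tree(8, rng=rng)
        labels = tree.tip_labels
        states = {t: int(rng.integers(0, 2)) for t in labels}
        base = fitch_parsimony(tree, states).min_changes
        perm = dict(zip(labels, np.array(labels)[rng.permutation(len(labels))]))
        permuted_states = {perm[t]: states[t] for t in labels}
        relabeled = PhyloTree.from_newick(tree.as_newick())
        for leaf in relabeled.dtree.leaf_node_iter():
            leaf.taxon.label = perm[leaf.taxon.label]
        # same tree shape with permuted labels carrying their states along
        assert fitch_parsimony(PhyloTree(relabeled.dtree), permuted_states).min_changes == base


class TestCaminSokal:
    def test_fig1_three_independent_gains(self, fig1):
        tree, states = fig1
        rec = camin_sokal_parsimony(tree, states)
        assert rec.min_changes == 3
        assert rec.n_mp_labelings == 1
        gains = {frozenset(c) for c in rec.labelings[0].gains}
        assert gains == {
            frozenset(["Trentepohliales"]),
            frozenset(["Dasycladales"]),
            frozenset(["Cladophorales", "Blastophysa"]),
        }
        assert rec.n_losses == 0

    def test_monophyletic_gain(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rec = camin_sokal_parsimony(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert rec.min_changes == 1
        assert rec.labelings[0].gains == [frozenset(["A", "B"])]

    def test_matches_loss_free_brute_force(self, rng):
        for _ in range(40):
            tree = simulate_tree(int(rng.integers(4, 13)), rng=rng)
            states = {t: int(rng.integers(0, 2)) for t in tree.tip_labels}
            rec = camin_sokal_parsimony(tree, states)
            best, _ = brute_force_min_changes(tree, states, True, root_state=0)
            assert rec.min_changes == best

    def test_never_cheaper_than_fitch(self, rng):
        """Forbidding reversals can only increase the minimum change count."""
        for _ in range(30):
            tree = simulate_tree(int(rng.integers(4, 11)), rng=rng)
            states = {t: int(rng.integers(0, 2)) for t in tree.tip_labels}
            assert (
                fitch_parsimony(tree, states).min_changes
                <= camin_sokal_parsimony(tree, states).min_changes
            )


class TestBMAncestral:
    def test_two_tip_symmetric(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        est = bm_ancestral_ml(tree, {"A": 0.2, "B": 0.8})
        assert est.root_value[0] == pytest.approx(0.5)

    def test_two_tip_inverse_length_weighting(self):
        tree = PhyloTree.from_newick("(A:1,B:3);")
        est = bm_ancestral_ml(tree, {"A": 0.2, "B": 0.8})
        expected = (0.2 / 1 + 0.8 / 3) / (1 + 1 / 3)
        assert est.root_value[0] == pytest.approx(expected)

    def test_star_tree_weighted_mean(self):
        tree = PhyloTree.from_newick("(A:1,B:2,C:4);")
        est = bm_ancestral_ml(tree, {"A": 0.0, "B": 0.7, "C": 1.0})
        expected = (0.0 / 1 + 0.7 / 2 + 1.0 / 4) / (1 + 0.5 + 0.25)
        assert est.root_value[0] == pytest.approx(expected)

    def test_fewer_than_two_tips_errors(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            bm_ancestral_ml(tree, {"A": 0.5})

    def test_matches_explicit_gls_solution(self, rng):
        """Laplacian solve equals the phylogenetic-covariance GLS formula."""
        for _ in range(10):
            tree = simulate_tree(10, rng=rng)
            tips, _ = simulate_bm_on_tree(tree, 0.5, 0.02, rng)
            est = bm_ancestral_ml(tree, {t: v.item() for t, v in tips.items()})
            _assert_matches_gls(tree, tips, est, tol=1e-8)

    def test_constant_tips_give_zero_rate_and_constant_nodes(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        est = bm_ancestral_ml(tree, {t: 0.3 for t in "ABCD"})
        assert est.sigma2[0] == pytest.approx(0.0, abs=1e-12)
        for v in est.node_values.values():
            assert v[0] == pytest.approx(0.3)

    def test_affine_invariance(self, rng):
        tree = simulate_tree(8, rng=rng)
        tips, _ = simulate_bm_on_tree(tree, 0.0, 1.0, rng)
        vals = {t: v.item() for t, v in tips.items()}
        est = bm_ancestral_ml(tree, vals)
        est2 = bm_ancestral_ml(tree, {t: 3.0 * v - 1.0 for t, v in vals.items()})
        for clade, v in est.node_values.items():
            assert est2.node_values[clade][0] == pytest.approx(3.0 * v[0] - 1.0)
        assert est2.sigma2[0] == pytest.approx(9.0 * est.sigma2[0])

    def test_missing_tips_pruned(self, rng):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        est = bm_ancestral_ml(tree, {"A": 0.1, "B": 0.5, "C": 0.9})
        assert est.root_clade() == frozenset("ABC")

    def test_agrees_with_ape_ace(self, tmp_path):
        """Ancestral states match R's ape::ace ML fit on a fixed example."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        nwk = "((A:1.0,B:0.5):0.6,(C:0.8,(D:0.4,E:0.3):0.5):0.2);"
        vals = {"A": 0.1, "B": 0.4, "C": 0.9, "D": 0.55, "E": 0.7}
        tree = PhyloTree.from_newick(nwk)
        est = bm_ancestral_ml(tree, vals)
        script = tmp_path / "ace.R"
        script.write_text(
            'library(ape)\n'
            f'tr <- read.tree(text="{nwk}")\n'
            "x <- c(A=0.1,B=0.4,C=0.9,D=0.55,E=0.7)\n"
            'a <- ace(x[tr$tip.label], tr, type="continuous", method="ML")\n'
            "nodes <- (length(tr$tip.label)+1):(length(tr$tip.label)+tr$Nnode)\n"
            "for (i in seq_along(nodes)) {\n"
            "  tips <- extract.clade(tr, nodes[i])$tip.label\n"
            '  cat(paste(sort(tips), collapse="|"), a$ace[i], "\\n")\n'
            "}\n"
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        for line in proc.stdout.strip().splitlines():
            clade_str, value = line.split()
            clade = frozenset(clade_str.split("|"))
            assert est.node_values[clade][0] == pytest.approx(float(value), abs=1e-4)


def _assert_matches_gls(tree, tips, est, tol):
    labels = tree.tip_labels
    x = np.array([tips[t].item() for t in labels])
    eps = 1e-8 * max(tree.height(), 1.0)
    depth = {}
    for nd in tree.dtree.preorder_node_iter():
        depth[nd] = (
            0.0
            if nd.parent_node is None
            else depth[nd.parent_node] + max(tree.branch_length(nd), eps)
        )
    leaves = list(tree.dtree.leaf_node_iter())

    def ancestors(nd):
        out = {}
        while nd is not None:
            out[nd] = depth[nd]
            nd = nd.parent_node
        return out

    anc = [ancestors(lf) for lf in leaves]
    n = len(leaves)
    C = np.empty((n, n))
    for i in range(n):
        C[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = max(d for nd, d in anc[i].items() if nd in anc[j])
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    mu = ones @ Cinv @ x / (ones @ Cinv @ ones)
    for nd in tree.dtree.preorder_node_iter():
        if nd.is_leaf():
            continue
        cov = np.array([max(d for m, d in ancestors(nd).items() if m in anc[i]) for i in range(n)])
        expected = mu + cov @ Cinv @ (x - mu * ones)
        clade = tree.clade_tips(nd)
        assert abs(est.node_values[clade][0] - expected) < tol


class TestRenormalizeSimplex:
    def test_already_on_simplex_unchanged(self):
        out, raw = renormalize_simplex(np.array([0.5, 0.3, 0.15, 0.05]))
        np.testing.assert_allclose(out, [0.5, 0.3, 0.15, 0.05])

    def test_clip_then_renormalize(self):
        out, raw = renormalize_simplex(np.array([0.6, 0.5, -0.05, 0.05]))
        np.testing.assert_allclose(out, np.array([0.6, 0.5, 0.0, 0.05]) / 1.15)
        np.testing.assert_allclose(raw, [0.6, 0.5, -0.05, 0.05])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            renormalize_simplex(np.array([-0.1, 0.0, -0.2, 0.0]))

    def test_low_rate_bm_root_close_to_truth(self, rng):
        """Simplex-valued BM with small variance: renormalised root near truth."""
        root = np.array([0.5, 0.3, 0.15, 0.05])
        tree = simulate_tree(12, rng=rng)
        scale = 5e-4 / max(tree.height(), 1e-9)  # sigma2 * depth = 5e-4 per trait
        errs = []
        for _ in range(20):
            tips, _ = simulate_bm_on_tree(tree, root, scale, rng)
            est = bm_ancestral_ml(tree, tips)
            out, _ = renormalize_simplex(est.root_value)
            errs.append(np.abs(out - root).sum())
        assert np.mean(errs) < 0.05
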