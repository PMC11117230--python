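import numpy as np
import pandas as pd
import pytest

import biphasic as bp
from conftest import pectinate_newick


def clade_label(tree, node):
    """Readable key for an internal node: sorted tip labels beneath it."""
    return "".join(sorted(tree.labels[j] for j in tree.clade_nodes(node)
                          if tree.labels[j]))


class TestBlombergK:
    def test_star_tree_exactly_one(self):
        star = bp.Phylogeny.from_newick("(A:2,B:2,C:2,D:2,E:2);")
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = pd.Series(rng.normal(size=5), index=list("ABCDE"))
            res = bp.blomberg_k(star, x, nperm=99, seed=0)
            assert res.K == pytest.approx(1.0, abs=1e-10)

    def test_bm_data_detected_as_signal(self):
        tree = bp.simulate_tree(32, 50.0, seed=1)
        x = bp.simulate_traits(tree, bp.EvolModel("BM"), seed=2)["d1"]
        res = bp.blomberg_k(tree, x, nperm=199, seed=3)
        assert res.p < 0.05

    def test_permutation_p_reproducible(self):
        tree = bp.simulate_tree(16, 30.0, seed=4)
        x = bp.simulate_traits(tree, bp.EvolModel("BM"), seed=5)["d1"]
        a = bp.blomberg_k(tree, x, nperm=199, seed=6)
        b = bp.blomberg_k(tree, x, nperm=199, seed=6)
        assert (a.K, a.p) == (b.K, b.p)

    def test_white_noise_low_k_on_imbalanced_tree(self):
        tree = bp.Phylogeny.from_newick(pectinate_newick(32))
        rng = np.random.default_rng(7)
        ks = [
            bp.blomberg_k(tree, pd.Series(rng.normal(size=32),
                                          index=tree.tip_labels), nperm=0).K
            for _ in range(100)
        ]
        assert np.mean(ks) < 0.6


class TestAsr:
    def test_constant_tips(self, balanced4):
        x = pd.Series(2.5, index=list("ABCD"))
        est = bp.asr_bm(balanced4, x)
        np.testing.assert_allclose(est.node_values.to_numpy(), 2.5, atol=1e-10)

    def test_two_tip_symmetry(self):
        t = bp.Phylogeny.from_newick("(A:1,B:1);")
        est = bp.asr_bm(t, pd.Series({"A": 0.0, "B": 2.0}))
        assert est.root_value.iloc[0] == pytest.approx(1.0)

    def test_joint_gaussian_conditioning_oracle(self):
        # independent oracle: full (tips+nodes) covariance built by
        # explicit root-path intersection, then Gaussian conditioning
        rng = np.random.default_rng(8)
        for rep in range(20):
            n = int(rng.integers(5, 9))
            tree = bp.simulate_tree(n, 10.0, seed=100 + rep)
            x = pd.Series(rng.normal(size=n), index=tree.tip_labels)

            def shared_path(u, v):
                pu = set(tree.path_to_root(u))
                length = 0.0
                w = v
                while w not in pu:
                    w = int(tree.parent[w])
                return float(tree.depths[w])

            m = tree.n_nodes
            cov = np.array([[shared_path(u, v) for v in range(m)] for u in range(m)])
            tips = tree.tip_indices
            nodes = tree.internal_indices
            Ctt = cov[np.ix_(tips, tips)]
            Cnt = cov[np.ix_(nodes, tips)]
            ones = np.ones(n)
            w = np.linalg.solve(Ctt, ones)
            mu = (w @ x.to_numpy()) / (w @ ones)
            expect = mu + Cnt @ np.linalg.solve(Ctt, x.to_numpy() - mu)

            est = bp.asr_bm(tree, x)
            np.testing.assert_allclose(
                est.node_values.to_numpy()[:, 0], expect, atol=1e-8
            )

    def test_estimates_within_global_tip_range(self):
        rng = np.random.default_rng(9)
        tree = bp.simulate_tree(20, 30.0, seed=10)
        x = pd.Series(rng.normal(size=20), index=tree.tip_labels)
        est = bp.asr_bm(tree, x)
        assert est.node_values.to_numpy().min() >= x.min() - 1e-9
        assert est.node_values.to_numpy().max() <= x.max() + 1e-9


class TestPhytoolsOracle:
    """Cross-check against the R reference implementations on one fixture."""

    def test_k_and_asr_match_r(self, tmp_path):
        import json
        import subprocess

        newick = "((A:1,(B:0.5,C:0.5):0.5):1,(D:1.4,E:1.4):0.6);"
        x = {"A": 0.3, "B": -1.2, "C": 2.0, "D": 0.7, "E": -0.4}
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(phytools)); suppressMessages(library(jsonlite))\n'
            f'tree <- read.tree(text="{newick}")\n'
            "x <- c(A=0.3, B=-1.2, C=2.0, D=0.7, E=-0.4)\n"
            'k <- phylosig(tree, x, method="K")\n'
            "anc <- fastAnc(tree, x)\n"
            'tips <- lapply(seq_along(anc), function(i) sort(extract.clade(tree, as.integer(names(anc)[i]))$tip.label))\n'
            "names(anc) <- sapply(tips, paste, collapse='')\n"
            "cat(toJSON(list(K=as.numeric(k), anc=as.list(anc)), digits=12))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        tree = bp.Phylogeny.from_newick(newick)
        xs = pd.Series(x)
        res = bp.blomberg_k(tree, xs, nperm=99, seed=0)
        assert res.K == pytest.approx(ref["K"][0], rel=1e-8)
        est = bp.asr_bm(tree, xs)
        for i in tree.internal_indices:
            key = clade_label(tree, i)
            assert est.node_values.loc[i].iloc[0] == pytest.approx(
                ref["anc"][key][0], rel=1e-8
            )


class TestPhylomorphospace:
    def test_star_tree_nodes_at_gls_mean(self):
        star = bp.Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(
            rng.normal(size=(4, 2)), index=list("ABCD"), columns=["PC1", "PC2"]
        )
        pms = bp.phylomorphospace(star, scores)
        np.testing.assert_allclose(
            pms.node_coords.to_numpy()[0], scores.mean(axis=0), atol=1e-10
        )

    def test_tips_pass_through_and_componentwise_asr(self):
        tree = bp.simulate_tree(10, 20.0, seed=12)
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(
            rng.normal(size=(10, 2)), index=tree.tip_labels, columns=["PC1", "PC2"]
        )
        pms = bp.phylomorphospace(tree, scores)
        pd.testing.assert_frame_equal(pms.tip_coords, scores.loc[pms.tip_coords.index])
        for col in scores.columns:
            single = bp.asr_bm(tree, scores[col])
            np.testing.assert_allclose(
                pms.node_coords[col].to_numpy(),
                single.node_values.to_numpy()[:, 0],
                atol=1e-12,
            )

    def test_missing_species_dropped(self):
        tree = bp.simulate_tree(8, 10.0, seed=14)
        rng = np.random.default_rng(15)
        scores = pd.DataFrame(
            rng.normal(size=(6, 2)), index=tree.tip_labels[:6], columns=["a", "b"]
        )
        pms = bp.phylomorphospace(tree, scores)
        assert len(pms.tip_coords) == 6


class TestStayton:
    def _pinned(self, balanced4):
        X = pd.DataFrame({"v": {"A": 0.0, "B": 4.0, "C": 0.5, "D": 6.0}})
        nv = {}
        for i in balanced4.internal_indices:
            nv[i] = {"ABCD": 2.0, "AB": 1.0, "CD": 3.0}[clade_label(balanced4, i)]
        return X, pd.DataFrame({"v": nv})

    def test_hand_enumerated_four_tip_case(self, balanced4):
        X, nv = self._pinned(balanced4)
        rep = bp.stayton_convergence(balanced4, X, ["A", "C"], nsim=0, node_values=nv)
        assert rep.C1 == pytest.approx(1 - 0.5 / 3.0, abs=1e-10)
        assert rep.C2 == pytest.approx(2.5, abs=1e-10)
        assert rep.C3 == pytest.approx(2.5 / 5.5, abs=1e-10)
        assert rep.C4 == pytest.approx(2.5 / 11.5, abs=1e-10)

    def test_identical_tips_give_c1_of_one(self, balanced4):
        X = pd.DataFrame({"v": {"A": 1.0, "B": 4.0, "C": 1.0, "D": -2.0}})
        rep = bp.stayton_convergence(balanced4, X, ["A", "C"], nsim=0)
        assert rep.C1 == pytest.approx(1.0)
        assert rep.C2 == pytest.approx(rep.C2)  # defined

    def test_sister_tips_maximal_distance_gives_zero(self):
        # A and B are sisters; with a midpoint ancestor the tip pair is
        # the largest distance on their two-edge history
        t = bp.Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        X = pd.DataFrame({"v": {"A": -1.0, "B": 1.0, "C": 0.0}})
        nv = {i: 0.0 for i in t.internal_indices}
        rep = bp.stayton_convergence(t, X, ["A", "B"], nsim=0,
                                     node_values=pd.DataFrame({"v": nv}))
        assert rep.C1 == pytest.approx(0.0, abs=1e-12)
        assert rep.C2 == pytest.approx(0.0, abs=1e-12)

    def test_c2_identity(self, balanced4):
        X, nv = self._pinned(balanced4)
        rep = bp.stayton_convergence(balanced4, X, ["A", "C"], nsim=0, node_values=nv)
        d_tip = 0.5
        d_max = d_tip + rep.C2
        assert rep.C1 == pytest.approx(1 - d_tip / d_max)

    def test_simulation_p_reproducible(self):
        tree = bp.simulate_tree(12, 20.0, seed=16)
        X = bp.simulate_traits(tree, bp.EvolModel("BM"), dims=2, seed=17)
        focal = tree.tip_labels[:3]
        a = bp.stayton_convergence(tree, X, focal, nsim=100, seed=18)
        b = bp.stayton_convergence(tree, X, focal, nsim=100, seed=18)
        assert (a.p1, a.p2, a.p3, a.p4) == (b.p1, b.p2, b.p3, b.p4)


class TestMultiTree:
    def test_identical_trees_zero_variance(self):
        tree = bp.simulate_tree(10, 15.0, seed=19)
        X = bp.simulate_traits(tree, bp.EvolModel("BM"), dims=2, seed=20)
        res = bp.multi_tree_convergence([tree] * 10, X, tree.tip_labels[:3], seed=21)
        assert res.n_used == 10
        assert res.values["C1"].std() == 0.0

    def test_tree_missing_focal_tips_skipped(self):
        trees = [bp.simulate_tree(8, 10.0, seed=s) for s in (22, 23)]
        X = bp.simulate_traits(trees[0], bp.EvolModel("BM"), dims=2, seed=24)
        other = trees[1]
        relabeled = bp.Phylogeny(other.parent, other.edge_length,
                                 [None if lb is None else lb + "_x"
                                  for lb in other.labels])
        res = bp.multi_tree_convergence(
            [trees[0], relabeled], X, trees[0].tip_labels[:2], seed=25
        )
        assert res.n_used == 1

    def test_quartiles_match_percentile_oracle(self):
        trees = [bp.simulate_tree(10, 15.0, seed=s) for s in range(30, 38)]
        X = bp.simulate_traits(trees[0], bp.EvolModel("BM"), dims=2, seed=26)
        focal = trees[0].tip_labels[:3]
        res = bp.multi_tree_convergence(trees, X, focal, seed=27)
        assert res.medians["C1"] == pytest.approx(
            np.percentile(res.values["C1"], 50), abs=1e-12
        )
        assert res.q1["C3"] == pytest.approx(
            res.values["C3"].quantile(0.25), abs=1e-12
        )


class TestDtt:
    def test_hand_interpolated_example(self, toy_tree):
        nv = pd.DataFrame({"v": {i: v for i, v in
                                 zip(toy_tree.internal_indices, [0.0, 1.0])}})
        # internal order: root (value 0) then (A,B) ancestor (value 1)
        x = pd.Series({"A": 2.0, "B": 0.0, "C": -1.0})
        prof = bp.dtt_profile(toy_tree, x, bin_edges=np.array([2.0, 1.0, 0.0]),
                              node_values=nv)
        assert prof.bin_midpoints[0] == pytest.approx(1.5)
        assert prof.disparity[0] == pytest.approx(0.140625, abs=1e-12)

    def test_present_day_midpoint_equals_tip_variance(self):
        tree = bp.simulate_tree(15, 20.0, seed=28)
        x = bp.simulate_traits(tree, bp.EvolModel("BM"), seed=29)["d1"]
        prof = bp.dtt_profile(tree, x, bin_edges=np.array([0.0, 0.0]))
        assert prof.disparity[0] == pytest.approx(x.to_numpy().var(ddof=0))

    def test_constant_trait_zero_profile(self):
        tree = bp.simulate_tree(10, 20.0, seed=30)
        x = pd.Series(3.0, index=tree.tip_labels)
        prof = bp.dtt_profile(tree, x)
        np.testing.assert_allclose(prof.disparity, 0.0, atol=1e-20)

    def test_midpoint_beyond_root_rejected(self, toy_tree):
        x = pd.Series({"A": 1.0, "B": 0.0, "C": 2.0})
        with pytest.raises(ValueError, match="root"):
            bp.dtt_profile(toy_tree, x, bin_edges=np.array([5.0, 4.0]))


class TestTraitgram:
    def test_tip_coordinates(self):
        tree = bp.simulate_tree(8, 12.0, seed=31)
        x = bp.simulate_traits(tree, bp.EvolModel("BM"), seed=32)["d1"]
        tg = bp.traitgram(tree, x)
        for i, lb in tg.tip_labels.items():
            assert tg.times[i] == pytest.approx(0.0, abs=1e-9)
            assert tg.values[i] == pytest.approx(x[lb])

    def test_root_matches_asr_and_edge_count(self):
        tree = bp.simulate_tree(9, 12.0, seed=33)
        x = bp.simulate_traits(tree, bp.EvolModel("BM"), seed=34)["d1"]
        tg = bp.traitgram(tree, x)
        est = bp.asr_bm(tree, x)
        assert tg.values[tree.root] == pytest.approx(est.root_value.iloc[0])
        assert len(tg.edges) == 2 * tree.n_tips - 2  # binary tree
        assert len(set(tg.edges)) == len(tg.edges)
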