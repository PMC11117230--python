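import numpy as np
import pandas as pd
import pytest

import biphasic as bp
from conftest import random_similarity


class TestGpa:
    def test_similarity_invariance_two_triangles(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        other = 2.0 * (tri @ rot90.T) + np.array([3.0, -1.0])
        aligned = bp.gpa(np.stack([tri, other]))
        a = aligned.coords.iloc[0].to_numpy()
        b = aligned.coords.iloc[1].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)
        assert bp.procrustes_distance(tri, other) < 1e-10

    def test_normalization_contract(self, template):
        rng = np.random.default_rng(0)
        configs = np.stack(
            [random_similarity(template + rng.normal(0, 0.02, template.shape), rng)
             for _ in range(6)]
        )
        aligned = bp.gpa(configs)
        pts = aligned.coords.to_numpy().reshape(6, -1, 2)
        np.testing.assert_allclose(pts.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose((pts**2).sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_consensus_recovery(self, template):
        rng = np.random.default_rng(1)
        configs = np.stack(
            [template + rng.normal(0, 0.01, template.shape) for _ in range(10)]
        )
        aligned = bp.gpa(configs)
        rmsd = np.sqrt(((aligned.mean_shape - template) ** 2).mean())
        assert rmsd < 0.005

    def test_gpa_invariant_to_input_similarity_transforms(self, template):
        rng = np.random.default_rng(2)
        base = np.stack(
            [template + rng.normal(0, 0.03, template.shape) for _ in range(8)]
        )
        ref = bp.gpa(base).coords.to_numpy()
        moved = np.stack([random_similarity(c, rng) for c in base])
        out = bp.gpa(moved).coords.to_numpy()
        # allow a global rotation between the two consensi
        a = ref.reshape(-1, 2)
        b = out.reshape(-1, 2)
        u, _, vt = np.linalg.svd(b.T @ a)
        rot = u @ np.diag([1, np.sign(np.linalg.det(u @ vt))]) @ vt
        np.testing.assert_allclose(b @ rot, a, atol=1e-8)

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((4, 2))
        good = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            bp.gpa(np.stack([flat, good]))


class TestProcrustesDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(6, 2))
            b = rng.normal(size=(6, 2))
            assert bp.procrustes_distance(a, a) < 1e-12
            assert bp.procrustes_distance(a, b) == pytest.approx(
                bp.procrustes_distance(b, a), abs=1e-12
            )

    def test_matches_rotation_grid_oracle(self):
        # brute-force minimization over a fine rotation grid
        rng = np.random.default_rng(4)
        grid = np.linspace(0, 2 * np.pi, 200001)
        for _ in range(20):
            a = rng.normal(size=(3, 2))
            b = rng.normal(size=(3, 2))
            sa = a - a.mean(0)
            sa /= np.sqrt((sa**2).sum())
            sb = b - b.mean(0)
            sb /= np.sqrt((sb**2).sum())
            cos_t = (sa * sb).sum()
            # distance at angle t: |sa - R(t) sb|^2 = 2 - 2(c cos t + s sin t)
            c = (sa * sb).sum()
            s = (sa[:, 0] * sb[:, 1] - sa[:, 1] * sb[:, 0]).sum()
            best = np.sqrt(np.min(2 - 2 * (c * np.cos(grid) + s * np.sin(grid))).clip(0))
            assert bp.procrustes_distance(a, b) == pytest.approx(best, abs=1e-4)


class TestLogShapeRatios:
    def _table(self, values, svl=None):
        idx = [f"sp{i}" for i in range(len(values))]
        df = pd.DataFrame(values, index=idx,
                          columns=[f"m{j}" for j in range(len(values[0]))])
        svl = pd.Series(svl if svl is not None else np.full(len(values), 30.0), index=idx)
        return bp.MeasurementTable(svl, df)

    def test_hand_example(self):
        lsr = bp.log_shape_ratios(self._table([[2.0, 4.0, 8.0]]))
        np.testing.assert_allclose(
            lsr.values.iloc[0], [-0.6931, 0.0, 0.6931], atol=1e-4
        )

    def test_equal_row_is_zero(self):
        lsr = bp.log_shape_ratios(self._table([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(lsr.values.iloc[0], 0.0, atol=1e-12)

    def test_size_invariance_and_zero_sum(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(1, 0.4, size=(6, 10))
        a = bp.log_shape_ratios(self._table(vals))
        b = bp.log_shape_ratios(self._table(vals * 7.0))
        pd.testing.assert_frame_equal(a.values, b.values)
        np.testing.assert_allclose(a.values.sum(axis=1), 0.0, atol=1e-9)

    def test_svl_carried_not_in_geomean(self):
        lsr = bp.log_shape_ratios(self._table([[2.0, 8.0]], svl=[50.0]))
        assert lsr.log_svl.iloc[0] == pytest.approx(np.log(50.0))
        np.testing.assert_allclose(lsr.values.iloc[0], [-np.log(2), np.log(2)])

    def test_missing_rejected(self):
        t = self._table([[2.0, 4.0]])
        t.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            bp.log_shape_ratios(t)


class TestImputePca:
    def _wrap(self, arr):
        idx = [f"sp{i}" for i in range(arr.shape[0])]
        return bp.MeasurementTable(
            pd.Series(np.full(arr.shape[0], 30.0), index=idx),
            pd.DataFrame(arr, index=idx,
                         columns=[f"m{j}" for j in range(arr.shape[1])]),
        )

    def test_complete_table_unchanged(self):
        rng = np.random.default_rng(6)
        t = self._wrap(rng.lognormal(1, 0.3, (8, 5)))
        out = bp.impute_pca(t)
        pd.testing.assert_frame_equal(out.table.values, t.values)
        assert out.n_iter == 0

    def test_rank1_exact_recovery(self):
        row = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        col = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        full = np.outer(col, row)
        holed = full.copy()
        for i, j in [(0, 1), (2, 4), (4, 0)]:
            holed[i, j] = np.nan
        out = bp.impute_pca(self._wrap(holed), n_components=1, tol=1e-12)
        np.testing.assert_allclose(out.table.values.to_numpy(), full, atol=1e-6)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(7)
        arr = rng.lognormal(1, 0.3, (12, 6))
        holed = arr.copy()
        mask = rng.random(arr.shape) < 0.15
        mask[:, 0] &= False  # keep one full column
        holed[mask] = np.nan
        out = bp.impute_pca(self._wrap(holed), n_components=2)
        got = out.table.values.to_numpy()
        np.testing.assert_array_equal(got[~mask], arr[~mask])

    def test_noisy_rank2_rmse(self):
        rng = np.random.default_rng(8)
        n, p, noise = 60, 8, 0.01
        base = rng.normal(size=(n, 2)) @ rng.normal(size=(2, p))
        truth = 20.0 + base + rng.normal(0, noise, (n, p))
        assert (truth > 0).all()
        mask = rng.random((n, p)) < 0.10
        holed = truth.copy()
        holed[mask] = np.nan
        out = bp.impute_pca(self._wrap(holed), n_components=2)
        err = out.table.values.to_numpy()[mask] - truth[mask]
        assert np.sqrt((err**2).mean()) < 3 * noise


class TestProcrustesVariance:
    def test_identical_rows_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert bp.procrustes_variance(X) == 0.0

    def test_hand_computation(self):
        assert bp.procrustes_variance(np.array([[0.0], [2.0]])) == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 6))
        shifted = X + rng.normal(size=(1, 6))
        assert bp.procrustes_variance(X) == pytest.approx(
            bp.procrustes_variance(shifted)
        )

    def test_loop_oracle_and_groups(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(10, 6)),
                         index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["a"] * 4 + ["b"] * 5 + ["c"], index=X.index)
        res = bp.procrustes_variance(X, groups)
        for g, members in X.groupby(groups).groups.items():
            sub = X.loc[members].to_numpy()
            if len(sub) < 2:
                assert np.isnan(res[g])
                continue
            mean = sub.mean(axis=0)
            oracle = np.mean([((r - mean) ** 2).sum() for r in sub])
            assert res[g] == pytest.approx(oracle, abs=1e-12)
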