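"""Correlation matrices, correlation-PCA, transition grids."""

import numpy as np
import pandas as pd
import pytest

from buridan import (Trajectory, ValidationError, confidence_ellipse,
                     correlation_matrix, pca_metrics, transition_grid)
from buridan.analysis import _ring_kernel
from buridan.metrics import MetricSet

from conftest import burst_from_points


def _table(rng, n=20, k=6, prefix="m"):
    data = {f"{prefix}{i}": rng.normal(size=n) for i in range(k)}
    df = pd.DataFrame(data)
    df.insert(0, "id", [f"f{i}" for i in range(n)])
    df.insert(1, "group", "WT")
    return df


class TestCorrelation:
    def test_duplicated_metric_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        df = _table(rng)
        df["m0_copy"] = df["m0"]
        res = correlation_matrix(df)
        assert res.r.loc["m0", "m0_copy"] == pytest.approx(1.0)
        assert res.significant.loc["m0", "m0_copy"]

    def test_symmetric_unit_diagonal_bounded(self):
        res = correlation_matrix(_table(np.random.default_rng(1)))
        r = res.r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_constant_metric_excluded_with_warning(self):
        df = _table(np.random.default_rng(2))
        df["flat"] = 3.14
        with pytest.warns(UserWarning, match="flat"):
            res = correlation_matrix(df)
        assert "flat" not in res.metrics and "flat" in res.dropped

    def test_too_few_individuals(self):
        with pytest.raises(ValidationError):
            correlation_matrix(_table(np.random.default_rng(3), n=2))

    def test_type_i_error_rate_near_alpha(self):
        """Independent metrics: ~5% of pairs flagged at alpha = 0.05."""
        rng = np.random.default_rng(4)
        flagged = total = 0
        for _ in range(150):
            res = correlation_matrix(_table(rng, n=20, k=6), alpha=0.05)
            mask = res.significant.to_numpy()
            iu = np.triu_indices_from(mask, k=1)
            flagged += mask[iu].sum()
            total += len(iu[0])
        rate = flagged / total
        assert 0.03 <= rate <= 0.07

    def test_invariant_under_metric_reordering(self):
        df = _table(np.random.default_rng(5))
        cols = ["id", "group", "m3", "m0", "m5", "m1", "m4", "m2"]
        a = correlation_matrix(df)
        b = correlation_matrix(df[cols])
        for x in a.metrics:
            for y in a.metrics:
                assert a.r.loc[x, y] == pytest.approx(b.r.loc[x, y])


class TestPCA:
    def test_eigenvalue_sum_equals_metric_count(self):
        res = pca_metrics(_table(np.random.default_rng(6), n=25, k=7))
        assert res.eigenvalues.sum() == pytest.approx(7.0)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_dominant_direction_wins(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=30)
        df = pd.DataFrame({f"m{i}": latent * (i + 1) + 0.05 * rng.normal(size=30)
                           for i in range(5)})
        res = pca_metrics(df)
        assert res.variance_fraction[0] > max(res.variance_fraction[1:])
        assert res.variance_fraction[0] > 0.9

    def test_matches_eigendecomposition_oracle(self):
        """Cross-check against a direct eigensolve of the correlation matrix."""
        rng = np.random.default_rng(8)
        df = _table(rng, n=20, k=11)
        res = pca_metrics(df)
        data = df.drop(columns=["id", "group"]).to_numpy()
        corr = np.corrcoef(data, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        # sklearn eigenvalues use the (n-1) covariance of z-scores = corr
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-8)

    def test_st_metrics_discarded(self):
        rng = np.random.default_rng(9)
        cols = {f.name: rng.normal(size=10) for f in
                __import__("dataclasses").fields(MetricSet)
                if f.name not in ("id", "group")}
        df = pd.DataFrame(cols)
        df.insert(0, "id", [str(i) for i in range(10)])
        df.insert(1, "group", "WT")
        res = pca_metrics(df)
        assert not any(m.startswith("st_") for m in res.metrics)

    def test_scores_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(10)
        df = _table(rng)
        a = pca_metrics(df)
        df2 = df.copy()
        df2["m2"] = df2["m2"] * 7.3 - 100.0
        b = pca_metrics(df2)
        for pc in ("PC1", "PC2"):
            x, y = a.scores[pc].to_numpy(), b.scores[pc].to_numpy()
            sign = np.sign(np.dot(x, y)) or 1.0
            np.testing.assert_allclose(x, sign * y, atol=1e-8)

    def test_too_few_individuals(self):
        with pytest.raises(ValidationError):
            pca_metrics(_table(np.random.default_rng(11), n=2))

    def test_confidence_ellipse_scales_with_level(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(50, 2))
        _, w80, _ = confidence_ellipse(pts, 0.8)
        _, w95, _ = confidence_ellipse(pts, 0.95)
        assert np.all(w95 > w80)


class TestTransitionGrid:
    def test_stationary_individual_single_bin(self):
        traj = Trajectory(bursts=[burst_from_points([(10.0, -5.0)] * 50)])
        grid = transition_grid([traj])
        assert (grid.raw > 0).sum() == 1
        assert grid.raw.sum() == 50

    def test_total_count_conserved(self):
        rng = np.random.default_rng(13)
        trajs = [Trajectory(bursts=[burst_from_points(
            rng.uniform(-58, 58, size=(100, 2)))]) for _ in range(3)]
        grid = transition_grid(trajs)
        assert grid.raw.sum() == 300

    def test_blur_conserves_mass(self):
        rng = np.random.default_rng(14)
        traj = Trajectory(bursts=[burst_from_points(
            rng.uniform(-58, 58, size=(500, 2)))])
        grid = transition_grid([traj])
        assert grid.blurred.sum() == pytest.approx(grid.raw.sum(), abs=1e-9)

    def test_rim_samples_binned(self):
        # samples exactly on the +R rim must not fall off the grid
        traj = Trajectory(bursts=[burst_from_points([(58.5, 0.0)] * 10)])
        assert transition_grid([traj]).raw.sum() == 10

    def test_kernel_ring_weights(self):
        k = _ring_kernel((21.0, 16.0, 4.0, 1.0))
        assert k.shape == (7, 7)
        assert k.sum() == pytest.approx(1.0)
        center = k[3, 3]
        assert center / k[3, 4] == pytest.approx(21 / 16)
        assert center / k[3, 5] == pytest.approx(21 / 4)
        assert center / k[3, 6] == pytest.approx(21 / 1)

    def test_ceiling_is_95_quantile_of_nonzero_blur(self):
        rng = np.random.default_rng(15)
        traj = Trajectory(bursts=[burst_from_points(
            rng.normal(0, 15, size=(2000, 2)))])
        grid = transition_grid([traj])
        nz = grid.blurred[grid.blurred > 0]
        assert grid.ceiling == pytest.approx(np.quantile(nz, 0.95))

    def test_invariant_under_concatenation_order(self):
        rng = np.random.default_rng(16)
        trajs = [Trajectory(bursts=[burst_from_points(
            rng.uniform(-50, 50, size=(40, 2)))]) for _ in range(4)]
        a = transition_grid(trajs)
        b = transition_grid(trajs[::-1])
        np.testing.assert_array_equal(a.raw, b.raw)
        np.testing.assert_allclose(a.blurred, b.blurred)
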