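"""Tensor evaluation, argmax, and relative-likelihood regions."""

import itertools

import numpy as np
import pytest

import fedlik as fl
from fedlik.errors import MemoryLimitError, ModelMismatchError


def _grid(*axes, increment):
    return fl.GridSpec(axes=tuple(axes), increment=increment)


def _manual_tensor(values, *axes, increment=0.1, site_id="manual", n=10):
    grid = _grid(*axes, increment=increment)
    return fl.LogLikTensor(
        grid_fingerprint=grid.fingerprint,
        axis_names=grid.axis_names,
        axis_values=grid.axis_values(),
        increment=increment,
        values=np.asarray(values, dtype=float),
        site_id=site_id,
        n_observations=n,
    )


class TestEvaluateTensor:
    def test_single_cell_equals_log_likelihood(self, binary_spec, make_binary_dataset):
        ds = make_binary_dataset(n=40)
        grid = _grid(
            fl.build_axis(-0.4, -0.395, 0.01, name="intercept"),
            fl.build_axis(0.7, 0.705, 0.01, name="x"),
            increment=0.01,
        )
        t = fl.evaluate_tensor(ds, binary_spec, grid)
        assert t.shape == (1, 1)
        assert t.values[0, 0] == pytest.approx(
            fl.log_likelihood(ds, binary_spec, [-0.4, 0.7]), abs=1e-12
        )

    def test_matches_nested_loop_oracle(self, binary_spec, make_binary_dataset):
        """Every cell equals a per-cell call to log_likelihood."""
        ds = make_binary_dataset(n=20, seed=11)
        grid = _grid(
            fl.build_axis(-1.0, -0.2, 0.2, name="intercept"),
            fl.build_axis(0.2, 0.9, 0.2, name="x"),
            increment=0.2,
        )
        t = fl.evaluate_tensor(ds, binary_spec, grid, method="cells")
        vals = grid.axis_values()
        for i, j in itertools.product(range(t.shape[0]), range(t.shape[1])):
            expected = fl.log_likelihood(ds, binary_spec, [vals[0][i], vals[1][j]])
            assert t.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bitwise_chunk_invariance(self, spec, make_dataset):
        ds = make_dataset(n=30, seed=2)
        grid = _grid(
            fl.build_axis(-3.0, -1.0, 0.5, name="intercept"),
            fl.build_axis(0.0, 1.5, 0.5, name="hypertension"),
            fl.build_axis(-1.0, 0.5, 0.5, name="sex"),
            fl.build_axis(0.0, 0.1, 0.5, name="age"),
            increment=0.5,
        )
        t1 = fl.evaluate_tensor(ds, spec, grid, method="cells", chunk_cells=1)
        t2 = fl.evaluate_tensor(ds, spec, grid, method="cells", chunk_cells=1000)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_lattice_method_matches_cells(self, spec, make_dataset):
        """The sufficient-statistics decomposition regroups the same sums."""
        ds = make_dataset(n=80, seed=5)
        grid = _grid(
            fl.build_axis(-3.1, -1.0, 0.1, name="intercept"),
            fl.build_axis(-0.2, 1.5, 0.1, name="hypertension"),
            fl.build_axis(-1.0, 0.5, 0.1, name="sex"),
            fl.build_axis(0.0, 0.1, 0.1, name="age"),
            increment=0.1,
        )
        a = fl.evaluate_tensor(ds, spec, grid, method="cells")
        b = fl.evaluate_tensor(ds, spec, grid, method="lattice")
        np.testing.assert_allclose(b.values, a.values, atol=1e-9)
        assert np.max(np.abs(a.values)) > 0

    def test_values_never_positive_and_max_cached(self, spec, make_dataset):
        ds = make_dataset(n=60, seed=3)
        grid = _grid(
            fl.build_axis(-3.0, -1.0, 0.25, name="intercept"),
            fl.build_axis(0.0, 1.0, 0.25, name="hypertension"),
            fl.build_axis(-0.5, 0.5, 0.25, name="sex"),
            fl.build_axis(0.0, 0.05, 0.25, name="age"),
            increment=0.25,
        )
        t = fl.evaluate_tensor(ds, spec, grid)
        assert np.all(t.values <= 0.0)
        assert t.max_value == t.values.max()

    def test_grid_maximum_below_continuous_mle(self, spec, make_dataset):
        """No lattice point can beat the continuous maximum likelihood."""
        ds = make_dataset(n=400, seed=6)
        fit = fl.fit_local(ds, spec)
        grid = fl.build_grid_spec([fit], 0.02)
        t = fl.evaluate_tensor(ds, spec, grid, memory_limit_bytes=2**33)
        assert t.max_value <= fit.max_loglik + 1e-10

    def test_refining_never_lowers_maximum(self, binary_spec, make_binary_dataset):
        ds = make_binary_dataset(n=200, seed=7)
        fit = fl.fit_local(ds, binary_spec)
        coarse = fl.build_grid_spec([fit], 0.01)
        fine = fl.build_grid_spec([fit], 0.005)
        t_c = fl.evaluate_tensor(ds, binary_spec, coarse)
        t_f = fl.evaluate_tensor(ds, binary_spec, fine)
        assert t_f.max_value >= t_c.max_value

    def test_memory_ceiling_raises_before_allocating(self, spec, make_dataset):
        ds = make_dataset(n=10)
        grid = _grid(
            fl.build_axis(-50.0, 50.0, 0.001, name="intercept"),
            fl.build_axis(-50.0, 50.0, 0.001, name="hypertension"),
            fl.build_axis(-50.0, 50.0, 0.001, name="sex"),
            fl.build_axis(-50.0, 50.0, 0.001, name="age"),
            increment=0.001,
        )
        with pytest.raises(MemoryLimitError, match="streaming"):
            fl.evaluate_tensor(ds, spec, grid)

    def test_axis_name_mismatch_raises(self, spec, make_dataset):
        grid = _grid(
            fl.build_axis(-1.0, 0.0, 0.5, name="intercept"),
            fl.build_axis(-1.0, 0.0, 0.5, name="wrong"),
            fl.build_axis(-1.0, 0.0, 0.5, name="sex"),
            fl.build_axis(-1.0, 0.0, 0.5, name="age"),
            increment=0.5,
        )
        with pytest.raises(ModelMismatchError):
            fl.evaluate_tensor(make_dataset(), spec, grid)

    def test_artifact_round_trip_is_bitwise(self, spec, make_dataset, tmp_path):
        ds = make_dataset(n=40, seed=9)
        grid = _grid(
            fl.build_axis(-3.0, -1.0, 0.5, name="intercept"),
            fl.build_axis(0.0, 1.0, 0.5, name="hypertension"),
            fl.build_axis(-0.5, 0.5, 0.5, name="sex"),
            fl.build_axis(0.0, 0.05, 0.5, name="age"),
            increment=0.5,
        )
        t = fl.evaluate_tensor(ds, spec, grid)
        path = tmp_path / "site.llt"
        fl.save_tensor(t, path)
        back = fl.load_tensor(path)
        np.testing.assert_array_equal(back.values, t.values)
        assert back.grid_fingerprint == t.grid_fingerprint
        assert back.site_id == t.site_id
        assert back.n_observations == t.n_observations
        for a, b in zip(back.axis_values, t.axis_values):
            np.testing.assert_array_equal(a, b)


class TestArgmax:
    def test_unique_maximum_found(self):
        values = np.full((3, 4), -9.0)
        values[1, 2] = -1.0
        t = _manual_tensor(
            values,
            fl.build_axis(0.0, 0.2, 0.1, name="a"),
            fl.build_axis(0.0, 0.3, 0.1, name="b"),
        )
        idx, beta, mx = fl.argmax_cell(t)
        assert idx == (1, 2)
        assert mx == -1.0
        np.testing.assert_allclose(beta, [0.1, 0.2], atol=1e-12)

    def test_tie_breaks_to_lowest_row_major_index(self):
        t = _manual_tensor(
            np.full((3, 4), -2.0),
            fl.build_axis(0.0, 0.2, 0.1, name="a"),
            fl.build_axis(0.0, 0.3, 0.1, name="b"),
        )
        idx, _, _ = fl.argmax_cell(t)
        assert idx == (0, 0)

    def test_fine_grid_argmax_near_continuous_mle(
        self, binary_spec, make_binary_dataset
    ):
        """With nearly orthogonal axes, the lattice argmax lands within one
        increment of the continuous MLE and its value within 0.01 of the
        fitted maximum."""
        ds = make_binary_dataset(n=600, seed=13)
        fit = fl.fit_local(ds, binary_spec)
        inc = 0.005
        axes = tuple(
            fl.build_axis(e - 0.06, e + 0.06, inc, name=n)
            for e, n in zip(fit.estimates, fit.parameter_names)
        )
        t = fl.evaluate_tensor(ds, binary_spec, _grid(*axes, increment=inc))
        _, beta, mx = fl.argmax_cell(t)
        assert np.all(np.abs(beta - fit.estimates) <= inc + 1e-12)
        assert fit.max_loglik - mx <= 0.01
        assert mx <= fit.max_loglik + 1e-10


class TestLikelihoodRegion:
    def test_argmax_always_inside(self, spec, make_dataset):
        ds = make_dataset(n=50, seed=4)
        grid = _grid(
            fl.build_axis(-3.0, -1.0, 0.25, name="intercept"),
            fl.build_axis(0.0, 1.0, 0.25, name="hypertension"),
            fl.build_axis(-0.5, 0.5, 0.25, name="sex"),
            fl.build_axis(0.0, 0.05, 0.25, name="age"),
            increment=0.25,
        )
        t = fl.evaluate_tensor(ds, spec, grid)
        idx, _, _ = fl.argmax_cell(t)
        for threshold in (0.01, 0.147, 1.0):
            assert fl.relative_likelihood_region(t, threshold)[idx]

    def test_threshold_one_keeps_only_maxima(self):
        values = np.array([[-3.0, -1.0], [-1.0, -2.0]])
        t = _manual_tensor(
            values,
            fl.build_axis(0.0, 0.1, 0.1, name="a"),
            fl.build_axis(0.0, 0.1, 0.1, name="b"),
        )
        mask = fl.relative_likelihood_region(t, 1.0)
        np.testing.assert_array_equal(mask, values == -1.0)

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.5])
    def test_invalid_threshold_raises(self, threshold):
        t = _manual_tensor(
            np.array([[-1.0]]), fl.build_axis(0.0, 0.05, 0.1, name="a"),
            fl.build_axis(0.0, 0.05, 0.1, name="b"),
        )
        with pytest.raises(ValueError):
            fl.relative_likelihood_region(t, threshold)

    def test_quadratic_surface_matches_analytic_ellipsoid(self):
        """On an exactly quadratic log-likelihood the region is the ellipsoid
        (beta-mu)' I (beta-mu) <= -2 ln(threshold), cell for cell, and the
        interval projections match the closed form."""
        inc = 0.02
        ax_a = fl.build_axis(-1.0, 1.0, inc, name="a")
        ax_b = fl.build_axis(-0.8, 0.8, inc, name="b")
        info = np.array([[40.0, 8.0], [8.0, 30.0]])
        mu = np.array([ax_a.values[50], ax_b.values[40]])  # on-lattice centre
        A, B = np.meshgrid(ax_a.values, ax_b.values, indexing="ij")
        d = np.stack([A - mu[0], B - mu[1]], axis=-1)
        quad = np.einsum("...i,ij,...j->...", d, info, d)
        t = _manual_tensor(-0.5 * quad - 5.0, ax_a, ax_b, increment=inc)
        for threshold in (0.147, 0.5):
            mask = fl.relative_likelihood_region(t, threshold)
            np.testing.assert_array_equal(mask, quad <= -2.0 * np.log(threshold))
            # projection of the ellipsoid on axis j has half-width
            # sqrt(-2 ln c * (I^{-1})_jj)
            cov = np.linalg.inv(info)
            for j in range(2):
                lo, hi = fl.likelihood_interval(t, j, threshold)
                half = np.sqrt(-2.0 * np.log(threshold) * cov[j, j])
                assert lo == pytest.approx(mu[j] - half, abs=inc)
                assert hi == pytest.approx(mu[j] + half, abs=inc)
                assert lo <= mu[j] <= hi

    def test_conventional_and_chisquare_cutoffs_agree_on_smooth_surface(self):
        """0.147 versus exp(-q/2) with q the 95% chi-square(1) quantile move
        interval endpoints by at most one grid step."""
        inc = 0.01
        ax = fl.build_axis(-2.0, 2.0, inc, name="a")
        vals = -0.5 * 25.0 * (ax.values - 0.0) ** 2
        t = _manual_tensor(vals, ax, increment=inc)
        for j in (0,):
            lo1, hi1 = fl.likelihood_interval(t, j, 0.147)
            lo2, hi2 = fl.likelihood_interval(t, j, fl.likelihood_threshold(0.95))
            assert abs(lo1 - lo2) <= inc + 1e-12
            assert abs(hi1 - hi2) <= inc + 1e-12

    def test_single_cell_region_degenerates(self):
        values = np.array([[-5.0, -1.0], [-6.0, -7.0]])
        t = _manual_tensor(
            values,
            fl.build_axis(0.0, 0.1, 0.1, name="a"),
            fl.build_axis(0.0, 0.1, 0.1, name="b"),
        )
        for axis in (0, 1):
            lo, hi = fl.likelihood_interval(t, axis, 1.0)
            assert lo == hi


def test_likelihood_threshold_value():
    """exp(-q/2) at the 95% chi-square(1) quantile is 0.1465 — the value the
    conventional 14.7% cutoff rounds."""
    assert fl.likelihood_threshold(0.95) == pytest.approx(0.146500, abs=5e-7)
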