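import numpy as np
import pytest

from gaitdyn.attractor import EmbeddingParams, embed
from gaitdyn.divergence import (DivergenceCurve, DivergenceError,
                                fit_exponent, lds_aci_per_axis,
                                nearest_neighbors, rosenstein_curve,
                                tuning_sweep)
from gaitdyn.synthgait import SyntheticConfig, generate_lumbar_accel, \
    generate_stride_intervals

SINE_PERIOD = 47 * np.pi


def brute_force_curve(points, theiler, horizon):
    """Exhaustive O(T^2) reference: all-pairs nearest neighbor with
    temporal exclusion, then the mean-of-ln-distance curve with tail
    truncation and zero-distance exclusion."""
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    refs, nns = [], []
    for j in range(n):
        mask = np.abs(np.arange(n) - j) > theiler
        mask &= dist[j] > 0
        if mask.any():
            cands = np.where(mask)[0]
            refs.append(j)
            nns.append(cands[np.argmin(dist[j][cands])])
    refs, nns = np.array(refs), np.array(nns)
    mean_log = np.full(horizon + 1, np.nan)
    n_pairs = np.zeros(horizon + 1, dtype=int)
    for i in range(horizon + 1):
        ok = np.maximum(refs, nns) + i <= n - 1
        if not ok.any():
            break
        d = np.linalg.norm(points[refs[ok] + i] - points[nns[ok] + i], axis=1)
        nz = d > 0
        if nz.any():
            mean_log[i] = np.mean(np.log(d[nz]))
        n_pairs[i] = int(nz.sum())
    return mean_log, n_pairs, refs, nns


@pytest.fixture(scope="module")
def small_attractor():
    rng = np.random.default_rng(0)
    x = np.sin(2 * np.pi * np.arange(320) / 37.3) + 0.1 * rng.standard_normal(320)
    return embed(x, EmbeddingParams(dim=2, delay=9, theiler=10))


class TestOracleEquivalence:
    def test_curve_matches_brute_force(self, small_attractor):
        att = small_attractor
        horizon = 60
        curve = rosenstein_curve(att, horizon=horizon)
        ref_curve, ref_pairs, _, _ = brute_force_curve(
            att.points, att.params.theiler, horizon)
        assert np.array_equal(curve.n_pairs, ref_pairs)
        assert np.allclose(curve.mean_log_div, ref_curve, atol=1e-10,
                           equal_nan=True)

    def test_neighbor_search_matches_brute_force(self, small_attractor):
        att = small_attractor
        refs, nns = nearest_neighbors(att.points, att.params.theiler)
        _, _, brefs, bnns = brute_force_curve(att.points, att.params.theiler, 0)
        assert np.array_equal(refs, brefs)
        assert np.array_equal(nns, bnns)

    def test_theiler_exclusion_honored(self, small_attractor):
        att = small_attractor
        refs, nns = nearest_neighbors(att.points, att.params.theiler)
        assert np.all(np.abs(refs - nns) > att.params.theiler)

    def test_larger_attractor_500_points(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.standard_normal(520))
        att = embed(x, EmbeddingParams(dim=3, delay=4, theiler=20))
        curve = rosenstein_curve(att, horizon=40)
        ref_curve, ref_pairs, _, _ = brute_force_curve(att.points, 20, 40)
        assert np.allclose(curve.mean_log_div, ref_curve, atol=1e-10,
                           equal_nan=True)


class TestRosensteinCurve:
    def test_flat_on_limit_cycle(self):
        # pure sine embedded as a circle (m=2, tau=T/4): constant-speed
        # orbit, no divergence; "drop" mode keeps the averaged set fixed
        x = np.sin(2 * np.pi * np.arange(18750) / SINE_PERIOD)
        att = embed(x, EmbeddingParams(dim=2, delay=37, theiler=75))
        curve = rosenstein_curve(att, incomplete="drop")
        for fit_range in [(0, 0.5), (0, 2), (2, 5), (5, 12)]:
            assert abs(fit_exponent(curve, fit_range)) < 1e-3

    def test_curve_shape_contract(self, small_attractor):
        curve = rosenstein_curve(small_attractor, horizon=100)
        assert len(curve.mean_log_div) == 101
        assert curve.n_pairs[0] > 0
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_default_horizon_length(self):
        x = np.sin(2 * np.pi * np.arange(18750) / SINE_PERIOD)
        att = embed(x, EmbeddingParams(dim=2, delay=37, theiler=75))
        curve = rosenstein_curve(att)
        assert len(curve.mean_log_div) == 1801
        assert curve.stride_axis[-1] == pytest.approx(12.0)

    def test_drop_mode_constant_pair_count(self, small_attractor):
        curve = rosenstein_curve(small_attractor, horizon=50, incomplete="drop")
        assert np.all(curve.n_pairs == curve.n_pairs[0])


class TestFitExponent:
    def _line_curve(self, slope, n=1801):
        x = np.arange(n) / 150.0
        return DivergenceCurve(slope * x, np.ones(n, dtype=int))

    def test_exact_line(self):
        assert fit_exponent(self._line_curve(0.02), (5, 12)) == pytest.approx(
            0.02, abs=1e-12)

    def test_three_point_secant(self):
        curve = self._line_curve(0.5)
        a = 1.0
        b = a + 2.0 / 150.0  # exactly 3 samples
        assert fit_exponent(curve, (a, b)) == pytest.approx(0.5, abs=1e-9)

    def test_range_validation(self):
        curve = self._line_curve(0.1)
        with pytest.raises(DivergenceError):
            fit_exponent(curve, (5, 5))
        with pytest.raises(DivergenceError):
            fit_exponent(curve, (5, 13))

    def test_too_few_points_errors(self):
        curve = self._line_curve(0.1)
        curve.mean_log_div[10:] = np.nan
        curve.n_pairs[10:] = 0
        with pytest.raises(DivergenceError, match="fewer than 3"):
            fit_exponent(curve, (5, 12))


class TestLdsAciPerAxis:
    @pytest.fixture(scope="class")
    def lumbar(self):
        cfg = SyntheticConfig(n_strides=140, structure="persistent", hurst=0.8,
                              seed=17)
        series, _ = generate_stride_intervals(cfg)
        return generate_lumbar_accel(series, cfg)

    def test_output_layout(self, lumbar):
        out = lds_aci_per_axis(lumbar, ref_stride=8)
        assert set(out) == {"AP", "V", "ML", "norm"}
        assert np.isnan(out["norm"].lds)  # no LDS for the vector norm
        for axis in ("AP", "V", "ML"):
            assert np.isfinite(out[axis].lds)
        for axis in out:
            assert np.isfinite(out[axis].aci)

    def test_deterministic(self, lumbar):
        a = lds_aci_per_axis(lumbar, ref_stride=8)
        b = lds_aci_per_axis(lumbar, ref_stride=8)
        for axis in a:
            assert a[axis].aci == b[axis].aci
            assert (a[axis].lds == b[axis].lds) or (
                np.isnan(a[axis].lds) and np.isnan(b[axis].lds))

    def test_norm_aci_rotation_invariant(self, lumbar):
        from gaitdyn.preprocess import GaitRecording
        base = lds_aci_per_axis(lumbar, ref_stride=8)
        y = np.radians(25.0)
        rot = np.array([[np.cos(y), 0, np.sin(y)], [0, 1, 0],
                        [-np.sin(y), 0, np.cos(y)]])  # azimuth about V
        rolled = GaitRecording(rot @ lumbar.samples, lumbar.fs_hz)
        rotated = lds_aci_per_axis(rolled, ref_stride=8)
        assert rotated["norm"].aci == pytest.approx(base["norm"].aci, abs=1e-6)


class TestTuningSweep:
    def _fake_curves(self, slopes_by_condition, n_participants=6):
        x = np.arange(1801) / 150.0
        rng = np.random.default_rng(0)
        curves = {}
        for p in range(n_participants):
            for cond, slope in slopes_by_condition.items():
                s = slope * (1 + 0.2 * rng.standard_normal())
                for lap in ("out", "return"):
                    y = s * x + 0.01 * rng.standard_normal()
                    curves[(f"P{p}", cond, lap, "norm")] = DivergenceCurve(
                        y, np.ones(1801, dtype=int))
        return curves

    def test_single_range_one_row_per_axis(self):
        curves = self._fake_curves({"normal": 0.03, "metronome": 0.02})
        table = tuning_sweep(curves, [(5, 12)], n_boot=50)
        assert len(table) == 1
        assert set(table.columns) >= {"a", "b", "axis", "es", "icc"}

    def test_detects_condition_contrast(self):
        curves = self._fake_curves({"normal": 0.03, "metronome": 0.015})
        table = tuning_sweep(curves, [(5, 12), (2, 6)], n_boot=50)
        assert (table["es"] < 0).all()

    def test_unpaired_errors(self):
        x = np.arange(1801) / 150.0
        curves = {("P0", "normal", "out", "norm"):
                  DivergenceCurve(0.02 * x, np.ones(1801, dtype=int))}
        table = tuning_sweep(curves, [(5, 12)], n_boot=10)
        assert np.isnan(table["es"]).all()  # no pairs -> no effect size
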