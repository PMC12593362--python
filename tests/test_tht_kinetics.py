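"""ThT trace normalisation, T50, scaling-exponent and empirical-model fits."""

import numpy as np
import pytest

from synsplice import synthetic_data as sd
from synsplice import tht_kinetics as tk
from synsplice.tht_kinetics import ThTTrace


def make_trace(t, y, well="w"):
    return ThTTrace(np.asarray(t, float), np.asarray(y, float), well)


class TestNormalize:
    def test_well_max_constant(self):
        tr = make_trace(range(12), [3.0] * 12)
        assert np.allclose(tk.normalize_trace(tr).signal, 1.0)

    def test_dataset_max(self):
        tr = make_trace(range(12), np.linspace(0, 5, 12))
        out = tk.normalize_trace(tr, "dataset_max", group_max=10.0)
        assert out.signal.max() == pytest.approx(0.5)

    def test_recovers_scaled_model_curve(self):
        t = np.arange(0, 40, 0.5)
        y = tk.amyloid_curve(t, 0.05, 0.8, 1.0)
        tr = make_trace(t, 7.3 * y)
        out = tk.normalize_trace(tr)
        assert np.allclose(out.signal, y / y.max(), atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tk.normalize_trace(make_trace(range(12), [0.0] * 12))


class TestT50:
    def test_first_crossing_no_interpolation(self):
        tr = make_trace([0, 1, 2, 3], [0, 0.2, 0.6, 1.0])
        assert tk.t50(tr) == 2

    def test_flat_trace_not_reached(self):
        assert tk.t50(make_trace([0, 1, 2], [0.3, 0.3, 0.3])) is None

    def test_matches_dense_analytic_scan(self):
        t = np.arange(0, 45, 0.25)
        tr = make_trace(t, tk.amyloid_curve(t, 0.05, 0.8, 1.0))
        got = tk.t50(tk.normalize_trace(tr))
        dense = np.arange(0, 45, 1e-3)
        y = tk.amyloid_curve(dense, 0.05, 0.8, 1.0)
        t50_true = dense[np.argmax(y >= 0.5 * tr.signal.max())]
        assert abs(got - t50_true) <= 0.25   # within one sampling interval


class TestScaling:
    def test_exact_power_law(self):
        x = np.array([20, 40, 60, 80, 100], float)
        fit = tk.fit_scaling(list(zip(x, 2 * x**-0.5)))
        assert fit.gamma == pytest.approx(-0.5, abs=1e-9)
        assert fit.loglog_slope == pytest.approx(-0.5, abs=1e-9)

    def test_concentration_independent(self):
        x = [20, 40, 60, 80]
        fit = tk.fit_scaling([(c, 7.0) for c in x])
        assert fit.gamma == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(7)
        gammas = []
        for _ in range(50):
            x = np.array([20, 40, 60, 80, 100], float)
            y = 5 * x**-0.55 * (1 + 0.05 * rng.standard_normal(5))
            gammas.append(tk.fit_scaling(list(zip(x, y))).gamma)
        assert abs(np.mean(gammas) - (-0.55)) < 0.05

    def test_not_reached_excluded_with_warning(self):
        pts = [(20, 10.0), (40, 7.0), (60, 5.0), (80, None)]
        with pytest.warns(UserWarning):
            fit = tk.fit_scaling(pts)
        assert fit.n_points == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tk.fit_scaling([(20, 10.0), (40, 7.0)])


class TestEmpiricalModel:
    def test_lambda_zero_gives_flat_zero(self):
        assert np.allclose(tk.amyloid_curve(np.linspace(0, 50), 0.0, 1.0, 1.0),
                           0.0)

    def test_long_time_limit_is_one(self):
        assert tk.amyloid_curve(np.array([1e4]), 0.05, 0.8, 1.0)[0] == \
            pytest.approx(1.0)

    def test_monotone_nondecreasing(self):
        t = np.linspace(0, 60, 4000)
        for lam, kap, th in [(0.05, 0.8, 1.0), (0.2, 0.3, 2.5), (1e-3, 2, 0.4)]:
            y = tk.amyloid_curve(t, lam, kap, th)
            assert np.all(np.diff(y) >= -1e-12)

    def test_parameter_recovery(self):
        t = np.arange(0, 45, 0.25)
        traces = [sd.gen_tht(0.05, 0.8, 1.0, t, noise_sigma=0.01, seed=s)[0]
                  for s in range(3)]
        fits = tk.fit_empirical(traces, shared_theta=True)
        for f in fits:
            assert f.lam == pytest.approx(0.05, rel=0.10)
            assert f.kap == pytest.approx(0.8, rel=0.10)
            assert abs(f.theta - 1.0) < 0.2
        assert len({f.theta for f in fits}) == 1   # shared theta

    def test_time_rescaling_rescales_rates(self):
        """Compressing the time axis by a factor must scale fitted λ and κ
        up by the same factor (the model depends on κt and λ²e^{κt})."""
        t = np.arange(0, 45, 0.25)
        trace = sd.gen_tht(0.05, 0.8, 1.0, t, noise_sigma=0.005, seed=0)[0]
        fast = ThTTrace(trace.time / 2.0, trace.signal, "fast")
        f0 = tk.fit_empirical([trace])[0]
        f1 = tk.fit_empirical([fast])[0]
        assert f1.kap == pytest.approx(2 * f0.kap, rel=0.05)
        assert f1.lam == pytest.approx(2 * f0.lam, rel=0.15)

    def test_truncation_ignores_post_peak_decay(self):
        t = np.arange(0, 45, 0.25)
        clean = sd.gen_tht(0.05, 0.8, 1.0, t, noise_sigma=0.01, seed=3)[0]
        floc = sd.gen_tht(0.05, 0.8, 1.0, t, noise_sigma=0.01,
                          flocculation_rate=0.08, seed=3)[0]
        f_clean = tk.fit_empirical([clean])[0]
        f_floc = tk.fit_empirical([floc])[0]
        assert f_floc.kap == pytest.approx(f_clean.kap, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            tk.fit_empirical([make_trace(range(5), [0, 0.1, 0.3, 0.8, 1.0])])


class TestPelleting:
    @pytest.mark.parametrize("dsol,dwhole,expected", [
        (0.0, 50.0, 100.0), (50.0, 50.0, 0.0), (13.0, 100.0, 87.0)])
    def test_values(self, dsol, dwhole, expected):
        assert tk.pct_pelletable(dsol, dwhole) == pytest.approx(expected)

    def test_clipping_with_warning(self):
        with pytest.warns(UserWarning):
            assert tk.pct_pelletable(120.0, 100.0) == 0.0

    def test_nonpositive_whole_rejected(self):
        with pytest.raises(ValueError):
            tk.pct_pelletable(1.0, 0.0)


def test_plate_csv_round_trip(tmp_path):
    import pandas as pd
    t = np.arange(0, 10, 0.5)
    rows = [{"time_h": ti, "signal": float(i + ti), "well": f"W{i}",
             "variant": "FL", "conc_uM": 100, "nacl_mM": 0, "seeded": False}
            for i in range(2) for ti in t]
    path = tmp_path / "plate.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    traces = tk.read_plate_csv(path)
    assert len(traces) == 2
    assert traces[0].condition["variant"] == "FL"
    assert np.allclose(traces[1].signal, t + 1)
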