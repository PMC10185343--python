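"""Binding-curve inference: standard curves, Bmax, Hill fit, sRatio,
classification, % Resistance, heatmap assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from qflim import binding as bnd
from qflim import simulate as sim


def hill(a, kd, bmax):
    a = np.asarray(a, dtype=float)
    return bmax * a / (kd + a)


def roi_table(a_free, dw, donor=2.0):
    return pd.DataFrame(
        {
            "donor_conc": donor,
            "acceptor_total_conc": np.asarray(a_free, float),
            "acceptor_free_conc": np.asarray(a_free, float),
            "delta_omega": np.asarray(dw, float),
        }
    )


def grid_search_oracle(x, y, w=None):
    """Kd over a dense log grid; Bmax closed-form per Kd (weighted LS)."""
    w = np.ones_like(x) if w is None else w
    best = (None, np.inf)
    for kd in np.geomspace(0.01, 1000, 4000):
        u = x / (kd + x)
        bmax = np.sum(w * u * y) / np.sum(w * u * u)
        rss = np.sum(w * (y - bmax * u) ** 2)
        if rss < best[1]:
            best = (kd, rss)
    return best[0]


class TestStandardCurve:
    def test_exact_line(self):
        df = pd.DataFrame({"known_uM": [0, 1, 2], "measured_au": [0, 100, 200]})
        c = bnd.fit_standard_curve(df)
        assert c.slope == pytest.approx(100.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-9)
        assert c.concentration(150.0) == pytest.approx(1.5)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 9, 10)
        y = 100 * x + rng.normal(0, 5, 10)
        df = pd.DataFrame({"known_uM": x, "measured_au": y})
        slope_oracle = np.polyfit(x, y, 1)[0]
        c = bnd.fit_standard_curve(df)
        assert c.slope == pytest.approx(slope_oracle)
        assert c.slope == pytest.approx(100.0, rel=0.05)

    def test_degenerate_rejected(self):
        df = pd.DataFrame({"known_uM": [1, 1], "measured_au": [5, 6]})
        with pytest.raises(ValueError):
            bnd.fit_standard_curve(df)

    def test_inverse_floored_at_zero(self):
        c = bnd.StandardCurve(100.0, 50.0, 1.0)
        assert c.concentration(10.0) == 0.0


class TestFilterRois:
    def test_windows(self):
        df = pd.DataFrame(
            {
                "donor_conc": [0.5, 2.0, 2.0, 3.5],
                "acceptor_total_conc": [10.0, 20.0, 60.0, 10.0],
            }
        )
        kept = bnd.filter_rois(df)
        assert len(kept) == 1
        assert kept.donor_conc.iloc[0] == 2.0

    def test_matches_brute_scan(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "donor_conc": rng.uniform(0, 5, 500),
                "acceptor_total_conc": rng.uniform(0, 80, 500),
            }
        )
        brute = (
            (df.donor_conc >= 1) & (df.donor_conc <= 3) & (df.acceptor_total_conc <= 50)
        ).sum()
        assert len(bnd.filter_rois(df)) == brute


class TestBmaxAndFreeAcceptor:
    def test_median_example(self):
        df = roi_table([35, 40, 45], [0.06, 0.08, 0.10])
        bmax, n = bnd.estimate_bmax(df)
        assert (bmax, n) == (0.08, 3)

    def test_single_value_window(self):
        df = roi_table([40], [0.07])
        assert bnd.estimate_bmax(df)[0] == 0.07

    def test_empty_window_flagged(self):
        df = roi_table([5, 10], [0.02, 0.04])
        bmax, n = bnd.estimate_bmax(df)
        assert n == 0 and math.isnan(bmax)

    def test_noiseless_hill_window_median(self):
        a = np.linspace(30, 50, 21)
        df = roi_table(a, hill(a, 5.0, 0.1))
        bmax, _ = bnd.estimate_bmax(df)
        assert bmax == pytest.approx(hill(40.0, 5.0, 0.1), abs=1e-9)
        assert bmax == pytest.approx(0.088, abs=1e-2)

    def test_free_acceptor_formula(self):
        df = roi_table([10.0, 10.0, 10.0], [0.0, 0.1, 0.5], donor=2.0)
        out = bnd.free_acceptor(df, bmax=0.1)
        assert out[0] == pytest.approx(10.0)  # no signal: free = total
        assert out[1] == pytest.approx(8.0)  # saturated: total - donor
        assert out[2] == pytest.approx(8.0)  # clipped f <= 1, never negative


class TestBinning:
    def test_singleton_bins(self):
        df = roi_table([2.5, 7.0], [0.02, 0.05])
        curve = bnd.bin_binding_curve(df, bin_edges=(0, 5, 10))
        assert list(curve.n_roi) == [1, 1]
        assert list(curve.se) == [0.0, 0.0]
        assert list(curve.delta_omega) == [0.02, 0.05]

    def test_identical_rois_zero_se(self):
        df = roi_table([2.0, 2.0], [0.03, 0.03])
        curve = bnd.bin_binding_curve(df, bin_edges=(0, 5))
        assert curve.se[0] == 0.0

    def test_matches_brute_grouping(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 50, 300)
        y = rng.normal(0.05, 0.01, 300)
        df = roi_table(a, y)
        edges = np.arange(0, 55, 5.0)
        curve = bnd.bin_binding_curve(df, bin_edges=edges)
        idx = np.digitize(a, edges) - 1
        for xm, ym, n, b in zip(
            curve.a_free, curve.delta_omega, curve.n_roi, np.unique(idx)
        ):
            m = idx == b
            assert ym == pytest.approx(y[m].mean())
            assert n == m.sum()


class TestHillFit:
    def test_noiseless_recovery(self):
        a = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 40.0])
        curve = bnd.bin_binding_curve(roi_table(a, hill(a, 5.0, 0.1)), bin_edges=np.arange(0, 55, 1.0))
        fit = bnd.fit_hill(curve)
        assert fit.kd_apparent == pytest.approx(5.0, rel=0.01)
        assert fit.bmax == pytest.approx(0.1, rel=0.01)

    def test_half_saturation_identity(self):
        a = np.geomspace(0.5, 50, 12)
        curve = bnd.bin_binding_curve(roi_table(a, hill(a, 8.0, 0.12)), bin_edges=np.arange(0, 55, 1.0))
        fit = bnd.fit_hill(curve)
        assert fit.predict(fit.kd_apparent) == pytest.approx(fit.bmax / 2, rel=1e-6)

    def test_matches_grid_search_oracle(self):
        """20 random noiseless instances: fit within 2% of the log-grid
        search oracle."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            kd = rng.uniform(0.5, 80)
            bmax = rng.uniform(0.05, 0.3)
            a = np.sort(rng.uniform(0.5, 50, 12))
            y = hill(a, kd, bmax)
            curve = bnd.BindingCurve(a, y, np.zeros_like(a), np.ones(a.size, int))
            fit = bnd.fit_hill(curve, bmax_init=bmax)
            oracle = grid_search_oracle(a, y)
            assert fit.kd_apparent == pytest.approx(oracle, rel=0.02)

    def test_too_few_points_rejected(self):
        curve = bnd.BindingCurve(
            np.array([1.0, 2.0]), np.array([0.01, 0.02]), np.zeros(2), np.ones(2, int)
        )
        with pytest.raises(ValueError):
            bnd.fit_hill(curve)


class TestSRatio:
    def make(self, a, y):
        curve = bnd.BindingCurve(
            np.asarray(a, float), np.asarray(y, float),
            np.zeros(len(a)), np.ones(len(a), int),
        )
        fit = bnd.fit_hill(curve)
        return curve, fit

    def test_linear_data_near_one(self):
        a = np.linspace(1, 50, 12)
        curve, fit = self.make(a, 0.002 * a)
        s = bnd.compute_sratio(curve, fit)
        assert s == pytest.approx(1.0, abs=0.1)

    def test_hill_data_above_threshold(self):
        a = np.linspace(1, 50, 12)
        curve, fit = self.make(a, hill(a, 5.0, 0.1))
        assert bnd.compute_sratio(curve, fit) > bnd.SRATIO_THRESHOLD

    def test_constant_zero_degenerate(self):
        a = np.linspace(1, 50, 6)
        curve, fit = self.make(a, np.zeros(6))
        assert math.isnan(bnd.compute_sratio(curve, fit))


class TestClassification:
    def fit(self, converged=True):
        return bnd.HillFit(kd_apparent=5.0, bmax=0.1, converged=converged)

    def test_rules(self):
        assert bnd.classify_interaction(self.fit(), 1.6, True) == "binding"
        assert bnd.classify_interaction(self.fit(), 1.2, True) == "collision"
        assert bnd.classify_interaction(self.fit(), 1.6, False) == "indeterminate"
        assert bnd.classify_interaction(self.fit(converged=False), 5.0) == "indeterminate"

    def test_dynamic_range_gate(self):
        a = np.array([12.0, 15.0, 18.0])
        pos = bnd.BindingCurve(a, np.full(3, 0.10), np.zeros(3), np.ones(3, int))
        neg = bnd.BindingCurve(a, np.full(3, 0.02), np.zeros(3), np.ones(3, int))
        weak = bnd.BindingCurve(a, np.full(3, 0.06), np.zeros(3), np.ones(3, int))
        assert bnd.dynamic_range_check(pos, neg)[0] is True
        assert bnd.dynamic_range_check(weak, neg)[0] is False  # 0.04 <= 0.05
        assert bnd.dynamic_range_check(pos, pos)[0] is False
        out_of_window = bnd.BindingCurve(
            np.array([30.0]), np.array([0.1]), np.zeros(1), np.ones(1, int)
        )
        ok, reason = bnd.dynamic_range_check(out_of_window, neg)
        assert ok is False and "window" in reason


class TestAnalyzeBinding:
    def test_end_to_end_roi_level(self):
        rois = sim.simulate_binding_rois(800, kd=6.0, seed=0)
        fit = bnd.analyze_binding(bnd.filter_rois(rois), n_boot=200, seed=0)
        assert fit.converged
        assert fit.kd_apparent == pytest.approx(6.0, rel=0.25)
        assert fit.classification == "binding"
        lo, hi = fit.ci90_kd
        assert lo < fit.kd_apparent < hi

    def test_bootstrap_reproducible(self):
        rois = sim.simulate_binding_rois(400, kd=8.0, seed=1)
        f1 = bnd.analyze_binding(bnd.filter_rois(rois), n_boot=100, seed=5)
        f2 = bnd.analyze_binding(bnd.filter_rois(rois), n_boot=100, seed=5)
        assert f1.ci90_kd == f2.ci90_kd


class TestPercentResistance:
    def test_identical_fits_100(self):
        f = bnd.HillFit(kd_apparent=6.0, bmax=0.1)
        assert bnd.percent_resistance(f, f).percent_resistance == pytest.approx(100.0)

    def test_worked_example_58_8(self):
        control = bnd.HillFit(kd_apparent=6.0, bmax=0.1)
        drug = bnd.HillFit(kd_apparent=13.0, bmax=0.1)
        res = bnd.percent_resistance(control, drug, donor_ref=2.0, ratio=2.0)
        assert res.percent_resistance == pytest.approx(58.8, abs=0.1)

    def test_zero_bmax_drug(self):
        control = bnd.HillFit(kd_apparent=6.0, bmax=0.1)
        drug = bnd.HillFit(kd_apparent=6.0, bmax=0.0)
        assert bnd.percent_resistance(control, drug).percent_resistance == 0.0

    def test_invariant_to_common_signal_rescaling(self):
        control = bnd.HillFit(kd_apparent=6.0, bmax=0.1)
        drug = bnd.HillFit(kd_apparent=13.0, bmax=0.07)
        base = bnd.percent_resistance(control, drug).percent_resistance
        for scale in (0.5, 2.0, 10.0):
            c2 = bnd.HillFit(kd_apparent=6.0, bmax=0.1 * scale)
            d2 = bnd.HillFit(kd_apparent=13.0, bmax=0.07 * scale)
            assert bnd.percent_resistance(c2, d2).percent_resistance == pytest.approx(base)

    def test_zero_control_rejected(self):
        control = bnd.HillFit(kd_apparent=6.0, bmax=0.0)
        drug = bnd.HillFit(kd_apparent=6.0, bmax=0.1)
        with pytest.raises(ValueError):
            bnd.percent_resistance(control, drug)


class TestHeatmap:
    def fit(self, kd, pair, drug="DMSO", dose=""):
        return bnd.HillFit(
            kd_apparent=kd, bmax=0.1, condition={"pair": pair, "drug": drug, "dose": dose}
        )

    def test_single_fit(self):
        table = bnd.assemble_kd_heatmap([self.fit(5.0, "PUMA:BCL-XL")])
        assert table.loc["DMSO", "PUMA:BCL-XL"] == 5.0

    def test_replicates_averaged(self):
        fits = [self.fit(k, "PUMA:BCL-XL") for k in (4.0, 5.0, 6.0)]
        table = bnd.assemble_kd_heatmap(fits)
        assert table.loc["DMSO", "PUMA:BCL-XL"] == pytest.approx(5.0)
        assert table.loc["DMSO", "PUMA:BCL-XL_n"] == 3

    def test_missing_condition_is_empty(self):
        fits = [
            self.fit(5.0, "PUMA:BCL-XL"),
            self.fit(20.0, "PUMA-d26:BCL-XL", drug="A-1331852", dose="2.5uM"),
        ]
        table = bnd.assemble_kd_heatmap(fits)
        assert math.isnan(table.loc["DMSO", "PUMA-d26:BCL-XL"])
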