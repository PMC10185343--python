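"""Binding-curve inference: apparent Kd, sRatio classification, % Resistance.

Per-ROI ``delta_omega`` values (the phasor-angle binding statistic) are
plotted against the free acceptor concentration and fit to a 1:1 Hill
curve::

    delta_omega(A_free) = Bmax * A_free / (Kd + A_free)

The saturation parameter Bmax is anchored on the median signal of the
30-50 uM free-acceptor window; the bound donor fraction implied by the
signal, ``f = clip(delta_omega / Bmax, 0, 1)``, converts total to free
acceptor, ``A_free = A_total - f * D_total``.  Genuine binding (a saturating
curve) is separated from diffusive collisions (a signal linear in acceptor)
by the sRatio -- the ratio of the residual sum of squares of the best
straight line through the origin to that of the Hill fit -- thresholded at
1.5.  Resistance of a complex to a competitive inhibitor is the ratio of the
fitted signal with and without drug evaluated at an acceptor:donor ratio of
two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "StandardCurve",
    "BindingCurve",
    "HillFit",
    "ResistanceResult",
    "DEFAULT_BIN_EDGES",
    "SRATIO_THRESHOLD",
    "fit_standard_curve",
    "filter_rois",
    "estimate_bmax",
    "free_acceptor",
    "bin_binding_curve",
    "fit_hill",
    "compute_sratio",
    "dynamic_range_check",
    "classify_interaction",
    "analyze_binding",
    "percent_resistance",
    "assemble_kd_heatmap",
]

#: Binding-curve bin edges in uM free acceptor.  Non-uniform: finer below
#: 10 uM so half-saturation of tight binders (Kd of a few uM) is resolved,
#: coarser toward the 30-50 uM saturation window.
DEFAULT_BIN_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)

#: Minimum sRatio for a saturating (binding) classification.
SRATIO_THRESHOLD = 1.5

#: Dynamic-range gate: positive minus negative control delta_omega in the
#: 10-20 uM window must exceed this.
DYNAMIC_RANGE_MIN = 0.05
DYNAMIC_RANGE_WINDOW = (10.0, 20.0)

BMAX_WINDOW = (30.0, 50.0)


@dataclass(frozen=True)
class StandardCurve:
    """Linear intensity-to-concentration map fitted from protein standards."""

    slope: float  # a.u. per uM
    intercept: float  # a.u.
    r_squared: float

    def concentration(self, intensity) -> np.ndarray | float:
        """Invert the curve; concentrations are floored at zero."""
        conc = (np.asarray(intensity, dtype=float) - self.intercept) / self.slope
        conc = np.maximum(conc, 0.0)
        return float(conc) if conc.ndim == 0 else conc


@dataclass
class BindingCurve:
    """Binned binding curve: per-bin mean delta_omega vs free acceptor."""

    a_free: np.ndarray  # bin mean free-acceptor concentration, uM
    delta_omega: np.ndarray  # bin mean signal
    se: np.ndarray  # standard error of the bin mean (0 for singleton bins)
    n_roi: np.ndarray
    condition: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.a_free)


@dataclass
class HillFit:
    """Result of fitting one condition's binding curve."""

    kd_apparent: float  # uM
    bmax: float  # delta_omega units
    hill_n: float = 1.0
    rss: float = float("nan")
    sratio: float = float("nan")
    ci90_kd: tuple[float, float] = (float("nan"), float("nan"))
    n_roi: int = 0
    classification: str = "indeterminate"
    converged: bool = True
    condition: dict = field(default_factory=dict)

    def predict(self, a_free) -> np.ndarray | float:
        a = np.asarray(a_free, dtype=float)
        y = self.bmax * a ** self.hill_n / (self.kd_apparent ** self.hill_n + a ** self.hill_n)
        return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class ResistanceResult:
    """Fraction of complexes surviving competitive-inhibitor challenge."""

    signal_control_at_ratio2: float
    signal_drug_at_ratio2: float
    percent_resistance: float


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Ordinary least-squares line through (known uM, measured a.u.) points.

    Expects columns ``known_uM`` and ``measured_au`` (positional fallback:
    first two columns).  At least two distinct concentrations are required.
    """
    if {"known_uM", "measured_au"}.issubset(standards.columns):
        x = standards["known_uM"].to_numpy(float)
        y = standards["measured_au"].to_numpy(float)
    else:
        x = standards.iloc[:, 0].to_numpy(float)
        y = standards.iloc[:, 1].to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    if slope <= 0:
        raise ValueError("standard curve slope must be positive")
    return StandardCurve(float(slope), float(intercept), r2)


def filter_rois(
    rois: pd.DataFrame,
    donor_window: tuple[float, float] = (1.0, 3.0),
    acceptor_max: float = 50.0,
) -> pd.DataFrame:
    """Retain ROIs in the physiological analysis windows.

    Donor concentration must lie in ``donor_window`` (1-3 uM by default) and
    total acceptor concentration in ``[0, acceptor_max]`` (0-50 uM).
    """
    m = (
        (rois["donor_conc"] >= donor_window[0])
        & (rois["donor_conc"] <= donor_window[1])
        & (rois["acceptor_total_conc"] >= 0.0)
        & (rois["acceptor_total_conc"] <= acceptor_max)
    )
    return rois.loc[m].reset_index(drop=True)


def estimate_bmax(
    rois: pd.DataFrame,
    window: tuple[float, float] = BMAX_WINDOW,
    axis: str = "acceptor_total_conc",
) -> tuple[float, int]:
    """Median delta_omega over the saturation window (30-50 uM acceptor).

    Returns ``(bmax, n_in_window)``; ``n_in_window == 0`` flags an empty
    window, in which case the caller falls back to a free-Bmax fit.
    """
    m = (rois[axis] >= window[0]) & (rois[axis] <= window[1])
    n = int(m.sum())
    if n == 0:
        return float("nan"), 0
    return float(rois.loc[m, "delta_omega"].median()), n


def free_acceptor(rois: pd.DataFrame, bmax: float) -> np.ndarray:
    """Free acceptor per ROI: ``A_free = max(0, A_total - f * D_total)``
    with the bound-fraction estimate ``f = clip(delta_omega / bmax, 0, 1)``."""
    if not bmax > 0:
        raise ValueError("bmax must be positive")
    f = np.clip(rois["delta_omega"].to_numpy(float) / bmax, 0.0, 1.0)
    a_free = rois["acceptor_total_conc"].to_numpy(float) - f * rois["donor_conc"].to_numpy(float)
    return np.maximum(a_free, 0.0)


def bin_binding_curve(
    rois: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    x_column: str = "acceptor_free_conc",
    condition: dict | None = None,
) -> BindingCurve:
    """Bin ROI-level delta_omega along the free-acceptor axis.

    Per retained (non-empty) bin: mean x, mean delta_omega, standard error
    of the mean (0 for singleton bins), and the ROI count.
    """
    if len(rois) == 0:
        raise ValueError("no ROIs to bin")
    edges = np.asarray(bin_edges, dtype=float)
    x = rois[x_column].to_numpy(float)
    y = rois["delta_omega"].to_numpy(float)
    idx = np.digitize(x, edges) - 1
    xs, ys, ses, ns = [], [], [], []
    for b in range(edges.size - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        xs.append(x[m].mean())
        ys.append(y[m].mean())
        ses.append(y[m].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0)
        ns.append(n)
    return BindingCurve(
        np.array(xs), np.array(ys), np.array(ses), np.array(ns, dtype=int),
        condition=dict(condition or {}),
    )


def _weights(se: np.ndarray) -> np.ndarray:
    """1/SE^2 weights with singleton bins given the smallest positive SE."""
    se = np.asarray(se, dtype=float).copy()
    pos = se[se > 0]
    se[se <= 0] = pos.min() if pos.size else 1.0
    return se


def fit_hill(
    curve: BindingCurve,
    bmax_init: float | None = None,
    bmax_bounds: tuple[float, float] | None = None,
    hill_n_free: bool = False,
) -> HillFit:
    """Weighted least-squares Hill fit of a binned binding curve.

    Kd is fit on a log scale so positivity is structural.  The Hill
    coefficient is fixed at 1 (1:1 binding) unless ``hill_n_free``.  When a
    saturation-window Bmax estimate is available it initializes the fit and
    bounds Bmax to [0.5x, 4x] of the estimate (capped at 0.6); otherwise
    Bmax is free.
    """
    x, y, se = curve.a_free, curve.delta_omega, curve.se
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct free-acceptor values")
    sigma = _weights(se)
    if bmax_init is None or not np.isfinite(bmax_init) or bmax_init <= 0:
        bmax_init = max(float(np.max(y)), 1e-3)
    if bmax_bounds is None:
        bmax_bounds = (1e-6, 0.6)
    lo = min(max(bmax_bounds[0], 1e-6), bmax_init)
    hi = max(bmax_bounds[1], bmax_init * (1 + 1e-9))

    try:
        if hill_n_free:
            def model(a, logkd, bmax, n):
                return bmax * a**n / (math.exp(logkd) ** n + a**n)

            p0 = [math.log(10.0), bmax_init, 1.0]
            bounds = ([math.log(1e-3), lo, 0.2], [math.log(1e4), hi, 4.0])
        else:
            def model(a, logkd, bmax):
                return bmax * a / (math.exp(logkd) + a)

            p0 = [math.log(10.0), bmax_init]
            bounds = ([math.log(1e-3), lo], [math.log(1e4), hi])
        popt, _ = curve_fit(
            model, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return HillFit(
            kd_apparent=float("nan"), bmax=float("nan"), converged=False,
            n_roi=int(curve.n_roi.sum()), classification="indeterminate",
            condition=curve.condition,
        )
    kd = math.exp(popt[0])
    bmax = float(popt[1])
    n = float(popt[2]) if hill_n_free else 1.0
    fit = HillFit(
        kd_apparent=kd, bmax=bmax, hill_n=n,
        n_roi=int(curve.n_roi.sum()), condition=curve.condition,
    )
    resid = (y - fit.predict(x)) / sigma
    fit.rss = float(np.sum(resid**2))
    return fit


def compute_sratio(curve: BindingCurve, hillfit: HillFit) -> float:
    """Curvature statistic: weighted RSS of the best straight line through
    the origin (the collision model, signal proportional to free acceptor)
    divided by the weighted RSS of the Hill fit.

    Returns ``inf`` when the Hill fit is exact but the line is not, and
    ``nan`` for degenerate (all-zero) data.
    """
    if not hillfit.converged:
        raise ValueError("sRatio requires a converged Hill fit")
    x, y = curve.a_free, curve.delta_omega
    w = 1.0 / _weights(curve.se) ** 2
    denom = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / denom if denom > 0 else 0.0
    rss_line = float(np.sum(w * (y - slope * x) ** 2))
    rss_hill = float(np.sum(w * (y - hillfit.predict(x)) ** 2))
    scale = float(np.sum(w * y * y))
    if scale == 0.0:
        return float("nan")  # constant-zero data: both models degenerate
    # the Hill family contains the origin line in the Kd -> inf limit, so its
    # best RSS cannot exceed the line's; the bounded fit may stop short of
    # the limit, so enforce the nesting explicitly.
    rss_hill = min(rss_hill, rss_line)
    if rss_hill == 0.0:
        return 1.0 if rss_line == 0.0 else float("inf")
    return rss_line / rss_hill


def dynamic_range_check(
    positive: BindingCurve,
    negative: BindingCurve,
    window: tuple[float, float] = DYNAMIC_RANGE_WINDOW,
    min_difference: float = DYNAMIC_RANGE_MIN,
) -> tuple[bool, str]:
    """Assay QC: positive minus negative control signal in the 10-20 uM
    free-acceptor window must exceed 0.05 for sufficient dynamic range."""
    diffs = []
    for curve, name in ((positive, "positive"), (negative, "negative")):
        m = (curve.a_free >= window[0]) & (curve.a_free <= window[1])
        if not m.any():
            return False, f"{name} curve has no bins in the {window} uM window"
        diffs.append(float(np.average(curve.delta_omega[m], weights=curve.n_roi[m])))
    diff = diffs[0] - diffs[1]
    if diff > min_difference:
        return True, f"dynamic range {diff:.3f} > {min_difference}"
    return False, f"dynamic range {diff:.3f} <= {min_difference}"


def classify_interaction(
    hillfit: HillFit, sratio: float, dynamic_range_ok: bool = True
) -> str:
    """binding / collision / indeterminate from fit convergence, sRatio and
    the dynamic-range QC."""
    if not hillfit.converged or not np.isfinite(sratio):
        return "indeterminate"
    if sratio >= SRATIO_THRESHOLD:
        return "binding" if dynamic_range_ok else "indeterminate"
    return "collision"


def analyze_binding(
    rois: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    bmax_window: tuple[float, float] = BMAX_WINDOW,
    refine_bmax: bool = True,
    n_boot: int = 500,
    seed: int = 0,
    dynamic_range_ok: bool = True,
    hill_n_free: bool = False,
    condition: dict | None = None,
) -> HillFit:
    """Full curve analysis for one condition's filtered ROI table.

    Pipeline: Bmax from the saturation-window median on the total-acceptor
    axis -> free-acceptor conversion -> one refinement pass re-estimating
    Bmax on the free-acceptor axis -> binning -> weighted Hill fit -> sRatio
    -> classification -> bootstrap 90% CI on Kd (percentile method over
    ``n_boot`` ROI resamples; skipped when ``n_boot == 0``).
    """
    rois = rois.reset_index(drop=True)

    def _single(df: pd.DataFrame, do_boot: bool) -> HillFit:
        bmax0, n_win = estimate_bmax(df, bmax_window, axis="acceptor_total_conc")
        if n_win == 0 or not bmax0 > 0:
            bmax0 = max(float(df["delta_omega"].max()), 1e-3)
            bounds = (1e-6, 0.6)
        else:
            if refine_bmax:
                df = df.assign(acceptor_free_conc=free_acceptor(df, bmax0))
                b1, n1 = estimate_bmax(df, bmax_window, axis="acceptor_free_conc")
                if n1 > 0 and b1 > 0:
                    bmax0 = b1
            bounds = (0.5 * bmax0, min(max(4.0 * bmax0, bmax0 + 1e-6), 0.6))
        df = df.assign(acceptor_free_conc=free_acceptor(df, bmax0))
        curve = bin_binding_curve(df, bin_edges, condition=condition)
        fit = fit_hill(curve, bmax_init=bmax0, bmax_bounds=bounds, hill_n_free=hill_n_free)
        if fit.converged:
            fit.sratio = compute_sratio(curve, fit)
            fit.classification = classify_interaction(fit, fit.sratio, dynamic_range_ok)
        if do_boot and fit.converged and n_boot > 0:
            rng = np.random.default_rng(seed)
            kds = []
            for _ in range(n_boot):
                sample = df.sample(n=len(df), replace=True, random_state=rng)
                try:
                    kds.append(_single(sample.reset_index(drop=True), False).kd_apparent)
                except (ValueError, RuntimeError):
                    continue
            kds = np.array([k for k in kds if np.isfinite(k)])
            if kds.size >= 10:
                fit.ci90_kd = (
                    float(np.percentile(kds, 5)), float(np.percentile(kds, 95))
                )
        return fit

    return _single(rois, True)


def percent_resistance(
    fit_control: HillFit,
    fit_drug: HillFit,
    donor_ref: float = 2.0,
    ratio: float = 2.0,
) -> ResistanceResult:
    """% of complexes that remain intact under competitive-inhibitor challenge.

    Both fitted curves are evaluated at the free-acceptor concentration
    corresponding to an acceptor:donor ratio of two at the reference donor
    level (2 uM, the midpoint of the 1-3 uM window); the percentage is the
    drug/control signal ratio, clipped to [0, 100].  Invariant to any common
    rescaling of the binding signal.
    """
    if not (fit_control.converged and fit_drug.converged):
        raise ValueError("both fits must have converged")
    a_star = ratio * donor_ref
    v_control = fit_control.predict(a_star)
    v_drug = fit_drug.predict(a_star)
    if abs(v_control) < 1e-12:
        raise ValueError("control signal at the evaluation point is zero")
    pct = float(np.clip(100.0 * v_drug / v_control, 0.0, 100.0))
    return ResistanceResult(v_control, v_drug, pct)


def assemble_kd_heatmap(fits) -> pd.DataFrame:
    """Heatmap table of apparent Kd: rows drug/dose, columns protein pair.

    Cells hold the mean apparent Kd over replicate fits (missing conditions
    stay empty); a parallel ``*_n`` column carries the replicate count.
    Condition metadata is read from each fit's ``condition`` dict (keys
    ``pair``, ``drug``, ``dose``).
    """
    rows = []
    for f in fits:
        c = f.condition
        rows.append(
            {
                "pair": c.get("pair", "?"),
                "treatment": f"{c.get('drug', 'DMSO')} {c.get('dose', '')}".strip(),
                "kd": f.kd_apparent,
            }
        )
    df = pd.DataFrame(rows)
    mean = df.pivot_table(index="treatment", columns="pair", values="kd", aggfunc="mean")
    count = df.pivot_table(index="treatment", columns="pair", values="kd", aggfunc="count")
    count = count.rename(columns={c: f"{c}_n" for c in count.columns})
    return pd.concat([mean, count], axis=1)
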