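"""In-vitro plate-reader computations.

Background-subtracted FRET efficiency with matched unlabeled-acceptor
controls::

    % FRET E = (1 - (F_DA - back) / (F_D - back)) * 100

competitive-displacement dose curves fit to a one-phase exponential decay,
and SMAC-mCherry mitochondrial release::

    % release = 100 * F_supernatant / (F_supernatant + F_pellet)

optionally normalized so a buffer control reads 0 and a detergent
(full-permeabilization) control reads 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PlateRecord",
    "ReleaseRecord",
    "percent_fret",
    "displacement_curve",
    "OnePhaseDecayFit",
    "percent_smac_release",
]


@dataclass(frozen=True)
class PlateRecord:
    """One well's reading series: background, donor-only (with unlabeled
    acceptor), and donor + labeled acceptor."""

    well: str
    back: np.ndarray
    f_d: np.ndarray
    f_da: np.ndarray
    condition: dict | None = None

    def __post_init__(self) -> None:
        for name in ("back", "f_d", "f_da"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 0:
                raise ValueError(f"{name} series is empty")
            if np.any(arr < 0):
                raise ValueError(f"{name} readings must be non-negative")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class ReleaseRecord:
    """Supernatant/pellet fluorescence for one release reaction, with
    optional detergent (full permeabilization) and buffer controls."""

    f_supernatant: float
    f_pellet: float
    detergent_control: tuple[float, float] | None = None  # (sup, pellet)
    buffer_control: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.f_supernatant < 0 or self.f_pellet < 0:
            raise ValueError("readings must be non-negative")


def _aggregate(series: np.ndarray, how: str, tail: int) -> float:
    if how == "final":
        return float(series[-1])
    if how == "mean-of-tail":
        return float(series[-tail:].mean())
    raise ValueError("aggregate must be 'final' or 'mean-of-tail'")


def percent_fret(rec: PlateRecord, aggregate: str = "mean-of-tail", tail: int = 5) -> float:
    """Background-subtracted FRET efficiency in percent.

    The three series are reduced to single values (default: mean of the last
    5 timepoints) before applying the formula.  Requires the donor signal to
    exceed background.
    """
    back = _aggregate(rec.back, aggregate, tail)
    f_d = _aggregate(rec.f_d, aggregate, tail)
    f_da = _aggregate(rec.f_da, aggregate, tail)
    if f_d - back <= 0:
        raise ValueError("donor signal does not exceed background")
    return (1.0 - (f_da - back) / (f_d - back)) * 100.0


@dataclass(frozen=True)
class OnePhaseDecayFit:
    """E(dose) = plateau + (e0 - plateau) * exp(-rate * dose)."""

    e0: float
    plateau: float
    rate: float

    def predict(self, dose) -> np.ndarray | float:
        y = self.plateau + (self.e0 - self.plateau) * np.exp(-self.rate * np.asarray(dose, float))
        return float(y) if y.ndim == 0 else y


def displacement_curve(doses, efficiencies) -> OnePhaseDecayFit:
    """Fit a one-phase exponential decay to %FRET vs inhibitor dose.

    The dose axis is linear concentration.  At least three distinct doses
    are required.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct doses")

    def model(d, e0, plateau, lograte):
        return plateau + (e0 - plateau) * np.exp(-math.exp(lograte) * d)

    span = float(y.max() - y.min())
    if span < 1e-6 * max(abs(y).max(), 1.0):
        # constant data: the rate is indistinguishable from zero
        return OnePhaseDecayFit(float(y.mean()), float(y.mean()), 0.0)
    scale = max(float(x.max()), 1e-9)
    p0 = [float(y[np.argmin(x)]), float(y[np.argmax(x)]), math.log(1.0 / scale)]
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"one-phase decay fit did not converge: {err}") from err
    return OnePhaseDecayFit(float(popt[0]), float(popt[1]), math.exp(popt[2]))


def percent_smac_release(rec: ReleaseRecord, normalize: bool = False) -> float:
    """SMAC-mCherry release in percent.

    Raw value ``100 * F_sup / (F_sup + F_pellet)``.  With ``normalize`` and
    both controls present, the raw value is rescaled so the buffer control
    maps to 0 and the detergent control to 100, then clipped to [0, 100].
    """
    total = rec.f_supernatant + rec.f_pellet
    if total <= 0:
        raise ValueError("supernatant + pellet must be positive")
    raw = 100.0 * rec.f_supernatant / total

    if normalize and rec.detergent_control and rec.buffer_control:
        det = 100.0 * rec.detergent_control[0] / sum(rec.detergent_control)
        buf = 100.0 * rec.buffer_control[0] / sum(rec.buffer_control)
        if det <= buf:
            raise ValueError("detergent control must release more than buffer control")
        raw = float(np.clip(100.0 * (raw - buf) / (det - buf), 0.0, 100.0))
    return raw
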