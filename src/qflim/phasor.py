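"""Phasor analysis of TCSPC decay histograms.

A decay histogram is mapped to a point in the phasor (polar) plot by a
discrete Fourier transform at the laser repetition frequency::

    g = sum_i c_i cos(w t_i) / sum_i c_i
    s = sum_i c_i sin(w t_i) / sum_i c_i,      w = 2 pi k / T

with ``t_i`` the time-bin centers, ``T`` the repetition period and ``k`` the
harmonic.  Single-exponential decays of lifetime ``tau`` fall on the universal
semicircle at ``g = 1/(1+(w tau)^2)``, ``s = w tau /(1+(w tau)^2)``; mixtures
fall on chords between their components, weighted by photon contribution.

The binding statistic used throughout the package, ``delta_omega``, is the
fractional decrease of the phasor polar angle of a sample relative to a
donor-only reference.  It is zero for unquenched donor and increases
monotonically with the fraction of donor molecules in the FRET-quenched
(bound) state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecayHistogram",
    "PhasorPoint",
    "CalibrationReference",
    "decay_to_phasor",
    "phasor_of_lifetime",
    "calibrate",
    "phase_lifetime",
    "delta_omega",
    "fret_efficiency",
    "mean_phasor",
]


@dataclass(frozen=True)
class DecayHistogram:
    """Per-ROI (or per-pixel) TCSPC photon counts over time bins.

    Parameters
    ----------
    counts
        Non-negative photon counts per time bin.
    bin_width
        Width of one time bin in ns.
    rep_period
        Laser repetition period in ns.  The bins are assumed to span
        ``[0, n_bins * bin_width]`` which must not exceed the period by
        more than one bin.
    """

    counts: np.ndarray
    bin_width: float
    rep_period: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("bin_width and rep_period must be positive")
        if counts.size * self.bin_width > self.rep_period + self.bin_width:
            raise ValueError("time bins exceed the repetition period")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def times(self) -> np.ndarray:
        """Bin centers in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PhasorPoint:
    """A point (g, s) in the phasor plot with its photon weight."""

    g: float
    s: float
    n_photons: float = 0.0

    @property
    def phase(self) -> float:
        """Polar angle atan2(s, g) in radians."""
        return math.atan2(self.s, self.g)

    @property
    def modulus(self) -> float:
        return math.hypot(self.g, self.s)


@dataclass(frozen=True)
class CalibrationReference:
    """Instrument standardization from a reference fluorophore.

    ``measured_ref`` is the phasor of a fluorophore of known single
    exponential lifetime ``known_lifetime_ref`` (fluorescein, 4.0 ns, is the
    conventional standard).  ``measured_zero`` optionally holds the phasor of
    a fully quenched reference (near-zero lifetime); it is used as a quality
    check -- after calibration it should map close to (1, 0) -- not as a
    second constraint.
    """

    measured_ref: PhasorPoint
    known_lifetime_ref: float
    rep_period: float
    harmonic: int = 1
    measured_zero: PhasorPoint | None = None


def decay_to_phasor(decay: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """Fourier-transform a decay histogram into phasor coordinates.

    Raises
    ------
    ValueError
        If the histogram contains no photons (the phasor is undefined).
    """
    total = decay.total_counts
    if total <= 0:
        raise ValueError("undefined phasor: histogram contains no photons")
    w = 2.0 * math.pi * harmonic / decay.rep_period
    t = decay.times
    g = float(np.dot(decay.counts, np.cos(w * t)) / total)
    s = float(np.dot(decay.counts, np.sin(w * t)) / total)
    return PhasorPoint(g, s, n_photons=total)


def phasor_of_lifetime(tau: float, rep_period: float, harmonic: int = 1) -> PhasorPoint:
    """Theoretical phasor of a single-exponential decay of lifetime ``tau``."""
    if tau < 0:
        raise ValueError("lifetime must be non-negative")
    wt = 2.0 * math.pi * harmonic / rep_period * tau
    d = 1.0 + wt * wt
    return PhasorPoint(1.0 / d, wt / d)


def calibrate(raw: PhasorPoint, ref: CalibrationReference) -> PhasorPoint:
    """Apply the instrument correction defined by a measured reference.

    The correction is the complex rotation-and-scale that maps the measured
    reference phasor onto the theoretical phasor of its known lifetime; the
    same correction is applied to every sample phasor of a session.
    """
    if ref.measured_ref.modulus <= 0:
        raise ValueError("reference phasor has zero modulus")
    target = phasor_of_lifetime(ref.known_lifetime_ref, ref.rep_period, ref.harmonic)
    corr = complex(target.g, target.s) / complex(ref.measured_ref.g, ref.measured_ref.s)
    z = complex(raw.g, raw.s) * corr
    return PhasorPoint(z.real, z.imag, n_photons=raw.n_photons)


def phase_lifetime(p: PhasorPoint, rep_period: float, harmonic: int = 1) -> float:
    """Phase lifetime tau_phi = tan(phase) / w.

    Only defined for calibrated phasors in the physical quadrant (g > 0).
    """
    if p.g <= 0:
        raise ValueError("phase lifetime undefined for g <= 0")
    w = 2.0 * math.pi * harmonic / rep_period
    return max(p.s / p.g / w, 0.0)


def delta_omega(sample: PhasorPoint, donor_only: PhasorPoint) -> float:
    """Fractional change in phasor angle relative to the donor-only reference.

    ``delta_omega = (phi_donor - phi_sample) / phi_donor`` with ``phi`` the
    polar angle.  Positive values indicate a shorter (FRET-quenched) sample
    lifetime; the statistic increases monotonically with the bound donor
    fraction at fixed free/bound lifetimes.
    """
    phi_d = donor_only.phase
    if phi_d <= 0:
        raise ValueError("donor-only reference must have positive phase")
    return (phi_d - sample.phase) / phi_d


def fret_efficiency(tau_sample: float, tau_donor: float) -> float:
    """FRET efficiency E = 1 - tau_sample / tau_donor.

    May be slightly negative for noisy samples; reported as-is.
    """
    if tau_donor <= 0:
        raise ValueError("donor lifetime must be positive")
    return 1.0 - tau_sample / tau_donor


def mean_phasor(points: list[PhasorPoint] | tuple[PhasorPoint, ...]) -> PhasorPoint:
    """Photon-weighted mean of phasor points.

    Equals the phasor of the concatenated histograms (linearity of the
    transform).
    """
    if not points:
        raise ValueError("no phasor points to average")
    wsum = sum(p.n_photons for p in points)
    if wsum <= 0:
        raise ValueError("total photon weight must be positive")
    g = sum(p.g * p.n_photons for p in points) / wsum
    s = sum(p.s * p.n_photons for p in points) / wsum
    return PhasorPoint(g, s, n_photons=wsum)
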