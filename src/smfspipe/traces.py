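"""Force-curve processing: baseline/bending correction, peak detection,
curve rejection, the inverse-WLC contour-length transformation with KDE
barrier finding, increment measurement, fingerprint screening, thermal
spring-constant calibration and cross-correlation alignment of barrier
diagrams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .polymer import KB, PolymerParams, wlc_inverse_contour

__all__ = [
    "CurveRejected",
    "ForceCurve",
    "ProcessedCurve",
    "Peak",
    "FingerprintSpec",
    "FingerprintMatch",
    "ContourRepresentation",
    "XYLANASE",
    "ILOV",
    "CBM",
    "preprocess",
    "detect_peaks",
    "RejectionLimits",
    "reject_curve",
    "transform_to_contour_space",
    "measure_increments",
    "screen_fingerprint",
    "calibrate_spring_constant",
    "align_barrier_diagrams",
]


class CurveRejected(Exception):
    """A curve cannot be processed further; `.reason` is machine readable."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ForceCurve:
    """One retraction trace as recorded: piezo position (nm) vs force (pN)."""

    piezo_position: np.ndarray
    force: np.ndarray
    spring_constant: float
    pulling_speed: float
    temperature: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.piezo_position, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if z.shape != f.shape or z.ndim != 1:
            raise ValueError("piezo_position and force must be equal-length 1-D arrays")
        if np.any(np.diff(z) < 0):
            raise ValueError("piezo_position must be monotone nondecreasing")
        if self.spring_constant <= 0 or self.pulling_speed <= 0:
            raise ValueError("spring_constant and pulling_speed must be > 0")
        object.__setattr__(self, "piezo_position", z)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class ProcessedCurve:
    """Baseline-corrected force vs tip-sample separation."""

    extension: np.ndarray
    force: np.ndarray
    baseline_offset: float
    spring_constant: float
    pulling_speed: float
    id: str = ""


@dataclass(frozen=True)
class Peak:
    """A detected rupture/unfolding peak: local force maximum + drop."""

    index: int
    extension: float
    force: float
    drop: float


@dataclass(frozen=True)
class FingerprintSpec:
    """Expected contour-length increment of a fingerprint domain, nm."""

    name: str
    expected: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


#: Screening windows for the fingerprint domains used in the experiments.
XYLANASE = FingerprintSpec("xylanase", 89.0, 5.0)
ILOV = FingerprintSpec("iLOV", 36.0, 3.0)
CBM = FingerprintSpec("CBM", 57.0, 4.0)


@dataclass(frozen=True)
class FingerprintMatch:
    found: bool
    name: str | None = None
    consumed: tuple[int, ...] = ()


@dataclass(frozen=True)
class ContourRepresentation:
    """Contour-length-space view of a curve segment.

    `contour` holds one Lc value per retained point (force above cutoff),
    `point_index` the index of each retained point in the processed
    arrays.  `density` is a fixed-bandwidth Gaussian KDE over `grid`,
    normalised to unit area, and `barriers` are its strict local maxima.
    """

    contour: np.ndarray
    point_index: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    barriers: np.ndarray
    bandwidth: float


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(curve: ForceCurve, baseline_fraction: float = 0.1) -> ProcessedCurve:
    """Zero the force to the trailing baseline and correct lever bending.

    The trailing `baseline_fraction` of the trace (after complex rupture)
    defines zero force; the tip-sample separation is the piezo position
    minus the cantilever deflection force/k.
    """
    if not 0 < baseline_fraction <= 0.5:
        raise ValueError("baseline_fraction must be in (0, 0.5]")
    f = curve.force
    if np.ptp(f) == 0:
        raise CurveRejected("no_baseline")
    n_base = max(1, int(round(baseline_fraction * f.size)))
    offset = float(np.mean(f[-n_base:]))
    f0 = f - offset
    extension = curve.piezo_position - f0 / curve.spring_constant
    return ProcessedCurve(
        extension=extension,
        force=f0,
        baseline_offset=offset,
        spring_constant=curve.spring_constant,
        pulling_speed=curve.pulling_speed,
        id=curve.id,
    )


# ---------------------------------------------------------------------------
# Peak detection and curve rejection
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the ends are not biased toward zero
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + x.size]
    return out


def detect_peaks(curve: ProcessedCurve, min_drop: float = 20.0,
                 smooth_window: int = 5, lookahead: int = 50,
                 min_separation: int = 20) -> list[Peak]:
    """Screen for rupture peaks as sudden drops in force.

    The force is smoothed with a short moving average; candidate local
    maxima are kept when the smoothed force falls by at least `min_drop`
    within `lookahead` points after the maximum.  Reported peak force and
    extension come from the raw trace near the smoothed maximum.
    """
    if min_drop <= 0:
        raise ValueError("min_drop must be > 0")
    f = np.asarray(curve.force, dtype=float)
    if f.size < 3:
        return []
    fs = _moving_average(f, smooth_window)
    idx, _ = find_peaks(fs, distance=max(1, min_separation))
    peaks: list[Peak] = []
    for i in idx:
        ahead = fs[i + 1:i + 1 + lookahead]
        if ahead.size == 0:
            continue
        drop = fs[i] - ahead.min()
        if drop < min_drop:
            continue
        # refine on the raw trace: a rupture is a one-sample cliff far
        # larger than the noise, so the point just before the steepest
        # single-step decrease carries the peak force without the upward
        # bias a local max-over-noise would introduce
        lo = max(0, i - smooth_window)
        hi = min(f.size - 1, i + smooth_window + 1)
        j = lo + int(np.argmin(np.diff(f[lo:hi + 1])))
        peaks.append(Peak(index=j, extension=float(curve.extension[j]),
                          force=float(f[j]), drop=float(drop)))
    peaks.sort(key=lambda p: p.extension)
    return peaks


@dataclass(frozen=True)
class RejectionLimits:
    """Sanity limits used to sort out nonspecific/multiple interactions."""

    min_peaks: int = 3
    max_force: float = 600.0
    min_final_extension: float | None = None
    max_final_extension: float | None = None
    max_peaks: int | None = None


def reject_curve(peaks: Sequence[Peak],
                 limits: RejectionLimits = RejectionLimits()) -> tuple[bool, str | None]:
    """Keep/reject verdict with a machine-readable reason.

    Curves with fewer than `min_peaks` peaks carry no clearly identifiable
    signal; force and distance limits remove nonspecific and multiple
    interactions.
    """
    if len(peaks) < limits.min_peaks:
        return False, "too_few_peaks"
    if limits.max_peaks is not None and len(peaks) > limits.max_peaks:
        return False, "too_many_peaks"
    if any(p.force > limits.max_force for p in peaks):
        return False, "force_out_of_range"
    final_ext = peaks[-1].extension
    if limits.min_final_extension is not None and final_ext < limits.min_final_extension:
        return False, "distance_out_of_range"
    if limits.max_final_extension is not None and final_ext > limits.max_final_extension:
        return False, "distance_out_of_range"
    return True, None


# ---------------------------------------------------------------------------
# Contour-length transformation
# ---------------------------------------------------------------------------

def _gaussian_kde_fixed(values: np.ndarray, grid: np.ndarray, bandwidth: float,
                        weights: np.ndarray | None = None) -> np.ndarray:
    """Fixed-bandwidth (optionally weighted) Gaussian KDE, unit area."""
    z = (grid[:, None] - values[None, :]) / bandwidth
    kern = np.exp(-0.5 * z * z)
    if weights is None:
        dens = kern.sum(axis=1) / values.size
    else:
        dens = kern @ (weights / weights.sum())
    return dens / (bandwidth * np.sqrt(2.0 * np.pi))


def transform_to_contour_space(curve: ProcessedCurve,
                               params: PolymerParams = PolymerParams(),
                               force_cutoff: float = 10.0,
                               bandwidth: float = 1.0,
                               grid_step: float = 0.2,
                               min_points: int = 20,
                               prominence_fraction: float = 0.02,
                               sensitivity_weighting: bool = True,
                               min_extension: float = 5.0) -> ContourRepresentation:
    """Transform a curve into contour-length space and locate barriers.

    Every point with force above `force_cutoff` is mapped to the contour
    length of the WLC passing through it (fixed persistence length); a
    Gaussian KDE with the given bandwidth over those contour values yields
    the barrier-position diagram whose local maxima mark the unfolding
    barriers.  Maxima with prominence below `prominence_fraction` of the
    global maximum are treated as noise.

    With `sensitivity_weighting` (default), each point's KDE contribution
    is weighted by its contour-length precision (dF/dLc)^2: near the force
    cutoff the inverse transform amplifies force noise by the huge local
    Jacobian dLc/dF, and unweighted low-force points scatter into spurious
    density maxima.  The weighting leaves noise-free barriers unchanged.
    """
    if force_cutoff <= 0:
        raise ValueError("force_cutoff must be > 0 (WLC inversion undefined at F <= 0)")
    # the contact region (tiny extension) carries no contour information:
    # a noise spike there inverts to a spuriously precise small Lc
    mask = (curve.force > force_cutoff) & (curve.extension > min_extension)
    if int(mask.sum()) < min_points:
        raise CurveRejected("too_few_points_above_cutoff")
    point_index = np.flatnonzero(mask)
    x = curve.extension[mask]
    contour = np.asarray(wlc_inverse_contour(curve.force[mask], x, params))
    weights = None
    if sensitivity_weighting:
        u = x / contour
        # |dF/dLc| at fixed extension for the Marko-Siggia relation
        dfdlc = (0.5 / (1.0 - u) ** 3 + 1.0) * x / contour**2
        weights = dfdlc * dfdlc
    lo = contour.min() - 5.0 * bandwidth
    hi = contour.max() + 5.0 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    density = _gaussian_kde_fixed(contour, grid, bandwidth, weights)
    pk, _ = find_peaks(density, prominence=prominence_fraction * density.max())
    barriers = grid[pk]
    return ContourRepresentation(
        contour=contour, point_index=point_index, grid=grid,
        density=density, barriers=barriers, bandwidth=bandwidth,
    )


def measure_increments(rep: ContourRepresentation) -> np.ndarray:
    """Consecutive contour-length increments between sorted barriers, nm."""
    b = np.sort(np.asarray(rep.barriers, dtype=float))
    if b.size < 2:
        return np.empty(0)
    return np.diff(b)


def screen_fingerprint(increments: Sequence[float], spec: FingerprintSpec,
                       allow_substep_summing: bool = False) -> FingerprintMatch:
    """Check whether the increment list contains the fingerprint gain.

    A match is a single increment within `expected +- tolerance`, or, when
    substep summing is enabled (domains that unfold through intermediates),
    a consecutive run of increments whose sum falls in the window.
    """
    inc = np.asarray(list(increments), dtype=float)
    lo, hi = spec.expected - spec.tolerance, spec.expected + spec.tolerance
    for i, v in enumerate(inc):
        if lo <= v <= hi:
            return FingerprintMatch(True, spec.name, (i,))
    if allow_substep_summing:
        for i in range(inc.size):
            total = inc[i]
            for j in range(i + 1, inc.size):
                total += inc[j]
                if total > hi:
                    break
                if lo <= total:
                    return FingerprintMatch(True, spec.name, tuple(range(i, j + 1)))
    return FingerprintMatch(False)


# ---------------------------------------------------------------------------
# Spring-constant calibration
# ---------------------------------------------------------------------------

def calibrate_spring_constant(deflection: np.ndarray, temperature: float = 298.15,
                              min_samples: int = 1000) -> float:
    """Thermal calibration: k = kB T / <dz^2> (equipartition theorem).

    `deflection` is the thermally fluctuating lever deflection in nm;
    returns the spring constant in pN/nm.
    """
    d = np.asarray(deflection, dtype=float)
    if d.size < min_samples:
        raise ValueError(f"need at least {min_samples} deflection samples")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    var = float(np.var(d))
    if var <= 0:
        raise ValueError("deflection variance must be > 0")
    return KB * temperature / var


# ---------------------------------------------------------------------------
# Barrier-diagram alignment
# ---------------------------------------------------------------------------

def align_barrier_diagrams(reps: Sequence[ContourRepresentation],
                           reference: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Align contour-length densities by cross-correlation.

    All representations must share a common grid.  Each curve's offset is
    the shift (nm, integer grid steps) that maximises its cross-correlation
    with the reference density; applying the offset to a curve's
    contour axis superimposes it on the reference.  Returns (offsets,
    master_density) where the master is the mean of the aligned densities.
    Empty densities are excluded with a warning (offset NaN).
    """
    if len(reps) < 2:
        raise ValueError("need at least 2 representations to align")
    grid = reps[reference].grid
    step = float(grid[1] - grid[0])
    for r in reps:
        if r.grid.shape != grid.shape or not np.allclose(r.grid, grid):
            raise ValueError("all representations must share a common grid")
    ref = reps[reference].density
    n = grid.size
    offsets = np.empty(len(reps))
    aligned = []
    for i, r in enumerate(reps):
        if not np.any(r.density > 0):
            warnings.warn(f"representation {i} has empty density; excluded from master")
            offsets[i] = np.nan
            continue
        corr = np.correlate(r.density, ref, mode="full")
        lag = int(np.argmax(corr)) - (n - 1)  # r.density shifted by +lag vs ref
        offsets[i] = -lag * step
        if lag >= 0:
            shifted = np.concatenate([r.density[lag:], np.zeros(lag)])
        else:
            shifted = np.concatenate([np.zeros(-lag), r.density[:n + lag]])
        aligned.append(shifted)
    master = np.mean(aligned, axis=0)
    return offsets, master
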