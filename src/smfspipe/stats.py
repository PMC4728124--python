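"""Counting statistics and censoring correction.

Exact (Clopper-Pearson) binomial confidence intervals for event-class
probabilities, two-sample Kolmogorov-Smirnov comparison of force
distributions, kernel density estimates with mode extraction, the
pairwise overlap probability P(fingerprint unfolds below rupture), and
the censoring correction of the doubles/singles binding-mode ratio.

The censoring problem: only curves whose fingerprint domain unfolded
before the complex rupture are accepted, so mechanically weaker event
classes (single ruptures) are undercounted.  The survival probability of
a class equals the overlap probability of the fingerprint unfolding
force distribution with that class's rupture-force distribution, and
dividing each observed class count by its survival probability restores
the uncensored ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EventCounts",
    "KDEstimate",
    "CorrectionResult",
    "BiasingReport",
    "clopper_pearson_interval",
    "ks_two_sample",
    "silverman_bandwidth",
    "force_distribution_kde",
    "overlap_probability",
    "censoring_weights",
    "correct_binding_mode_ratio",
    "biasing_report",
]


def clopper_pearson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval from beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1)  (0 when k = 0)
    upper = BetaInv(1-alpha/2; k+1, n-k)  (1 when k = n)
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class EventCounts:
    """Single/double event counts with exact confidence intervals."""

    n_single: int
    n_double: int
    alpha: float = 0.05
    ci_single: tuple[float, float] = (math.nan, math.nan)
    ci_double: tuple[float, float] = (math.nan, math.nan)

    @classmethod
    def from_counts(cls, n_single: int, n_double: int, alpha: float = 0.05
                    ) -> "EventCounts":
        n = n_single + n_double
        return cls(
            n_single=n_single, n_double=n_double, alpha=alpha,
            ci_single=clopper_pearson_interval(n_single, n, alpha),
            ci_double=clopper_pearson_interval(n_double, n, alpha),
        )

    @property
    def n(self) -> int:
        return self.n_single + self.n_double

    @property
    def p_single(self) -> float:
        return self.n_single / self.n

    @property
    def p_double(self) -> float:
        return self.n_double / self.n


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    p-value uses the asymptotic two-sample distribution with the standard
    effective sample size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def silverman_bandwidth(sample: np.ndarray) -> float:
    """Silverman's rule of thumb, robust (min of sd and IQR/1.34)."""
    x = np.asarray(sample, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return max(1e-3, 1e-3 * abs(float(x[0])) if x.size else 1e-3)
    return 0.9 * spread * x.size ** (-1 / 5)


@dataclass(frozen=True)
class KDEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mode: float


def force_distribution_kde(sample, bandwidth: float | None = None,
                           grid_points: int = 1025) -> KDEstimate:
    """Gaussian-kernel density estimate of a force sample with its mode.

    Bandwidth defaults to Silverman's rule; the mode is the grid argmax.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be nonempty")
    bw = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(x.min() - 6 * bw, x.max() + 6 * bw, grid_points)
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))
    return KDEstimate(grid=grid, density=density, bandwidth=bw,
                      mode=float(grid[int(np.argmax(density))]))


def overlap_probability(fingerprint_forces, rupture_forces,
                        fingerprint_weights=None) -> float:
    """P(fingerprint unfolding force < rupture force), ties counting 1/2.

    The mean over all pairs of the indicator; with `fingerprint_weights`
    the fingerprint sample is treated as a weighted empirical distribution
    (used to undo the censoring of the observed fingerprint forces).
    """
    a = np.asarray(fingerprint_forces, dtype=float)
    b = np.asarray(rupture_forces, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    order = np.argsort(a)
    a = a[order]
    if fingerprint_weights is None:
        w = np.full(a.size, 1.0 / a.size)
    else:
        w = np.asarray(fingerprint_weights, dtype=float)[order]
        w = w / w.sum()
    cw = np.concatenate([[0.0], np.cumsum(w)])
    lo = np.searchsorted(a, b, side="left")
    hi = np.searchsorted(a, b, side="right")
    # weight strictly below each b, plus half the weight tied with it
    below = cw[lo]
    tied = cw[hi] - cw[lo]
    return float(np.mean(below + 0.5 * tied))


def censoring_weights(observed_fingerprint_forces, all_rupture_forces,
                      ) -> np.ndarray:
    """Inverse-probability weights for the observed fingerprint forces.

    A fingerprint draw at force F is observed only when the complex
    survives past F, which happens with probability S_R(F) under the
    pooled rupture-force distribution.  Every trace terminates in an
    observable rupture, so S_R is estimable without censoring; weighting
    each observed fingerprint force by 1/S_R(F) recovers the uncensored
    fingerprint distribution.  Weights are clipped at the resolution of
    the rupture sample to keep the largest fingerprint forces stable.
    """
    f = np.asarray(observed_fingerprint_forces, dtype=float)
    r = np.sort(np.asarray(all_rupture_forces, dtype=float))
    if f.size == 0 or r.size == 0:
        raise ValueError("both samples must be nonempty")
    surv = 1.0 - np.searchsorted(r, f, side="right") / r.size
    return 1.0 / np.clip(surv, 1.0 / r.size, None)


@dataclass(frozen=True)
class CorrectionResult:
    """Censoring-corrected doubles/singles binding-mode ratio."""

    observed_ratio: float
    overlap_single: float
    overlap_double: float
    corrected_ratio: float
    bootstrap_interval: tuple[float, float]
    n_bootstrap: int


def correct_binding_mode_ratio(counts: EventCounts, overlap_single: float,
                               overlap_double: float,
                               bootstrap_replicates: int = 2000,
                               seed: int | None = None,
                               force_samples: dict | None = None,
                               ) -> CorrectionResult:
    """Inflate each class count by its fingerprint-survival probability.

    corrected = (n_double / overlap_double) / (n_single / overlap_single)

    The bootstrap interval (percentile, 95%) resamples the class counts
    binomially; when `force_samples` is supplied with keys
    ``fingerprint`` (+ optional ``fingerprint_weights``), ``singles`` and
    ``doubles``, each replicate also resamples the force samples and
    recomputes the overlap probabilities.
    """
    if not 0 < overlap_single <= 1 or not 0 < overlap_double <= 1:
        raise ValueError("overlap probabilities must be in (0, 1]")
    if counts.n_single == 0:
        raise ValueError("zero single events: doubles/singles ratio undefined")
    observed = counts.n_double / counts.n_single
    corrected = (counts.n_double / overlap_double) / (counts.n_single / overlap_single)

    rng = np.random.default_rng(seed)
    n = counts.n
    p_double = counts.p_double
    boot = np.empty(bootstrap_replicates)
    fp = w = s = d = None
    if force_samples is not None:
        fp = np.asarray(force_samples["fingerprint"], dtype=float)
        w = force_samples.get("fingerprint_weights")
        w = None if w is None else np.asarray(w, dtype=float)
        s = np.asarray(force_samples["singles"], dtype=float)
        d = np.asarray(force_samples["doubles"], dtype=float)
    for i in range(bootstrap_replicates):
        k_d = rng.binomial(n, p_double)
        k_s = n - k_d
        if k_s == 0 or k_d == 0:
            boot[i] = np.nan
            continue
        if fp is not None:
            idx = rng.integers(0, fp.size, fp.size)
            fp_b = fp[idx]
            w_b = None if w is None else w[idx]
            s_b = s[rng.integers(0, s.size, s.size)]
            d_b = d[rng.integers(0, d.size, d.size)]
            o_s = overlap_probability(fp_b, s_b, w_b)
            o_d = overlap_probability(fp_b, d_b, w_b)
        else:
            o_s, o_d = overlap_single, overlap_double
        boot[i] = (k_d / o_d) / (k_s / o_s)
    boot = boot[np.isfinite(boot)]
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if boot.size
              else (math.nan, math.nan))
    return CorrectionResult(
        observed_ratio=observed,
        overlap_single=overlap_single,
        overlap_double=overlap_double,
        corrected_ratio=corrected,
        bootstrap_interval=(float(lo), float(hi)),
        n_bootstrap=bootstrap_replicates,
    )


@dataclass(frozen=True)
class BiasingReport:
    """Comparison of fingerprint unfolding forces by final-event class."""

    mode_single: float
    mode_double: float
    ks_statistic: float
    ks_pvalue: float
    downward_shift: bool
    n_single: int
    n_double: int


def biasing_report(fingerprint_given_single, fingerprint_given_double,
                   bandwidth: float | None = None) -> BiasingReport:
    """Quantify fingerprint-force biasing between final-event classes.

    Curves terminating in the weaker (single) rupture can only retain
    fingerprint unfolding events below that rupture force, truncating the
    conditional fingerprint distribution; a downward shift of its mode
    relative to double-terminated curves is the signature that the two
    event classes have distinct mechanical stabilities fixed at binding.
    """
    fs = np.asarray(fingerprint_given_single, dtype=float)
    fd = np.asarray(fingerprint_given_double, dtype=float)
    if fs.size == 0 or fd.size == 0:
        raise ValueError("both conditional fingerprint samples must be nonempty")
    mode_s = force_distribution_kde(fs, bandwidth).mode
    mode_d = force_distribution_kde(fd, bandwidth).mode
    d, p = ks_two_sample(fs, fd)
    return BiasingReport(
        mode_single=mode_s, mode_double=mode_d,
        ks_statistic=d, ks_pvalue=p,
        downward_shift=mode_s < mode_d,
        n_single=fs.size, n_double=fd.size,
    )
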