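"""Logistic growth fitting and derived carrying-capacity statistics.

Biofilm coverage (or per-grain biomass area) in the porous device follows a
logistic trajectory: exponential early growth released from resource
constraints, an inflection, and saturation at a carrying capacity K set by
the local pore environment.  This module fits

    y(t) = K / (1 + exp(-r (t - t0)))

by nonlinear least squares with multi-start initialisation, and derives

* ``nK``, the dimensionless carrying capacity: K divided by the area of a
  fixed reference annulus around the grain, so grains of different size are
  comparable (larger tortuosity -> larger nK is the hypothesis under test);
* the exponential-phase doubling time from a log-linear fit over an early
  window;
* plateau/overshoot change points of a metric series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LogisticGrowthModel",
    "LogisticGrowthResults",
    "fit_logistic",
    "normalized_carrying_capacity",
    "doubling_time",
    "detect_plateau",
]


def logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


@dataclass(frozen=True)
class LogisticGrowthResults:
    """Fitted logistic parameters with uncertainties and diagnostics."""

    K: float
    r: float
    t0: float
    rse: float
    cov: np.ndarray
    nobs: int
    low_confidence: bool
    times: np.ndarray
    values: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (K, r, t0)."""
        d = np.diag(self.cov)
        return np.sqrt(np.where(d >= 0, d, np.nan))

    def predict(self, t):
        return logistic(np.asarray(t, float), self.K, self.r, self.t0)

    def conf_band(self, t, alpha: float = 0.05):
        """Delta-method 1-alpha confidence band for the mean curve."""
        t = np.asarray(t, float)
        e = np.exp(-self.r * (t - self.t0))
        denom = (1.0 + e) ** 2
        gK = 1.0 / (1.0 + e)
        gr = self.K * (t - self.t0) * e / denom
        gt0 = -self.K * self.r * e / denom
        J = np.stack([gK, gr, gt0], axis=-1)
        var = np.einsum("...i,ij,...j->...", J, self.cov, J)
        se = np.sqrt(np.clip(var, 0, None))
        z = stats.t.ppf(1 - alpha / 2, max(self.nobs - 3, 1))
        mean = self.predict(t)
        return mean - z * se, mean + z * se

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Logistic growth fit  y(t) = K / (1 + exp(-r (t - t0)))",
            f"  n obs : {self.nobs}    RSE : {self.rse:.4g}",
            f"  K  = {self.K:.6g}  (se {se[0]:.3g})",
            f"  r  = {self.r:.6g} 1/h  (se {se[1]:.3g})",
            f"  t0 = {self.t0:.6g} h  (se {se[2]:.3g})",
        ]
        if self.low_confidence:
            lines.append("  warning: sparse or one-sided sampling; low-confidence fit")
        return "\n".join(lines)


class LogisticGrowthModel:
    """Nonlinear least-squares logistic model of a growth series.

    Parameters
    ----------
    times, values : 1-D arrays (hours, response).  The response can be a
        coverage percentage or an area; the fit is scale-equivariant in y.

    Notes
    -----
    Initialisation: K0 = 1.05 max(y), t0_0 = time of half-max, r0 from the
    early log-linear slope; 8 jittered restarts, best SSR wins.
    """

    N_STARTS = 8

    def __init__(self, times, values):
        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size < 4:
            raise ValueError("need at least 4 observations for a 3-parameter fit")
        self.times = t
        self.values = y
        self.low_confidence = t.size < 5 or y[-1] < 0.8 * np.max(y) or np.max(y) <= 0

    def _starts(self, rng):
        t, y = self.times, self.values
        ymax = max(np.max(y), np.finfo(float).tiny)
        K0 = 1.05 * ymax
        t0_0 = float(t[np.argmin(np.abs(y - ymax / 2))])
        pos = y > 0.01 * ymax
        r0 = 0.05
        if np.sum(pos) >= 3:
            early = np.flatnonzero(pos)[: max(3, np.sum(pos) // 3)]
            slope = np.polyfit(t[early], np.log(y[early]), 1)[0]
            if np.isfinite(slope) and slope > 0:
                r0 = float(slope)
        yield (K0, r0, t0_0)
        for _ in range(self.N_STARTS - 1):
            yield (
                K0 * rng.uniform(0.7, 1.5),
                r0 * rng.uniform(0.3, 3.0),
                t0_0 + rng.uniform(-0.3, 0.3) * (t[-1] - t[0]),
            )

    def fit(self, seed: int = 0) -> LogisticGrowthResults:
        t, y = self.times, self.values
        rng = np.random.default_rng(seed)
        best = None
        for p0 in self._starts(rng):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = optimize.curve_fit(
                        logistic, t, y, p0=p0, maxfev=20000,
                        bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
                    )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((y - logistic(t, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise RuntimeError(
                "logistic fit failed to converge from all starts "
                f"(n={t.size}, ymax={np.max(y):.3g})"
            )
        ssr, popt, pcov = best
        rse = float(np.sqrt(ssr / max(t.size - 3, 1)))
        if popt[1] <= 0:
            self.low_confidence = True
        return LogisticGrowthResults(
            K=float(popt[0]), r=float(popt[1]), t0=float(popt[2]),
            rse=rse, cov=pcov, nobs=t.size,
            low_confidence=self.low_confidence, times=t, values=y,
        )


def fit_logistic(times, values, seed: int = 0) -> LogisticGrowthResults:
    """Convenience wrapper around :class:`LogisticGrowthModel`."""
    return LogisticGrowthModel(times, values).fit(seed=seed)


def normalized_carrying_capacity(
    K_mm2: float, grain_radius_mm: float, reference_width_um: float = 200.0
) -> float:
    """Dimensionless carrying capacity nK = K / A_ref.

    A_ref is the area of the annulus from the grain surface out to radius
    ``r + reference_width``; the reference width is held fixed across grains
    so nK compares how fully each grain exploits the same near-surface shell.
    """
    w_mm = reference_width_um / 1000.0
    a_ref = np.pi * ((grain_radius_mm + w_mm) ** 2 - grain_radius_mm**2)
    if a_ref <= 0:
        raise ValueError("reference annulus has zero area")
    return float(K_mm2 / a_ref)


def doubling_time(times, values, window_h: tuple[float, float] = (0.0, 50.0)) -> float:
    """Exponential-phase doubling time ln(2)/slope of ln(y) vs t.

    Returns ``inf`` for a flat series; raises if the window contains
    non-positive values (no exponential phase to measure).
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    sel = (t >= window_h[0]) & (t <= window_h[1])
    if np.sum(sel) < 2:
        raise ValueError("fewer than 2 points inside the window")
    if np.any(y[sel] <= 0):
        raise ValueError("non-positive values in the exponential window")
    slope = np.polyfit(t[sel], np.log(y[sel]), 1)[0]
    if slope <= 0:
        return float("inf")
    return float(np.log(2.0) / slope)


def detect_plateau(times, values, tolerance: float, window: int = 5):
    """Plateau onset and overshoot peak of a metric series.

    The slope series is the centred finite-difference gradient smoothed by a
    ``window``-point rolling mean.  The onset is the earliest time after
    which the smoothed slope magnitude stays within ``tolerance`` (units of
    value per hour) for the remainder of the series.

    Returns
    -------
    (onset_time or None, peak_time) where peak_time = argmax of the series.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.size < 10:
        raise ValueError("need at least 10 points to call a plateau")
    slope = np.gradient(y, t)
    kernel = np.ones(window) / window
    smoothed = np.convolve(slope, kernel, mode="same")
    flat = np.abs(smoothed) <= tolerance
    peak_time = float(t[np.argmax(y)])
    onset = None
    # earliest index from which flatness holds to the end (ignore the last
    # half-window where the rolling mean is truncated)
    ok_until = t.size - max(window // 2, 1)
    suffix_flat = np.logical_and.accumulate(flat[:ok_until][::-1])[::-1]
    idx = np.flatnonzero(suffix_flat)
    if idx.size and idx[0] > 0:
        onset = float(t[idx[0]])
    elif idx.size:  # flat from the very start: no growth-to-plateau transition
        onset = float(t[0])
    return onset, peak_time
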