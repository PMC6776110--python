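"""Colloid-filtration model of streamer width growth.

A streamer sieves suspended cells from the fluid that flows through it.
If a fraction ``beta`` of the cells advected at pore velocity ``v`` through
the streamer cross-section is retained, the streamer's mean width grows as

    W(t) = 2 * beta * v * C * V * t / pi

with ``C`` the bulk cell concentration and ``V`` the single-cell volume.
The model is linear in time and holds during the early phase, before the
streamer densifies, loses permeability, and its width plateaus.

`predict_width` evaluates the forward model with an uncertainty band from
``beta ± beta_sd``; `StreamerFiltrationModel` estimates ``beta`` from
observed width series by a through-origin regression restricted to the
pre-plateau window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FiltrationParams",
    "FiltrationResults",
    "StreamerFiltrationModel",
    "predict_width",
    "estimate_beta",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class FiltrationParams:
    """Physical inputs of the filtration model.

    beta : filtration efficiency, fraction of advected cells retained.
    beta_sd : spread of beta used for the uncertainty band.
    v_mm_s : mean pore fluid velocity, mm/s.
    cells_per_ml : bulk cell concentration.
    cell_volume_um3 : single-cell volume, µm³ (default 1 µm³).

    Unit algebra, asserted at construction:
    (mm/s) * (cells/mm³) * (mm³/cell) * s -> mm.
    """

    beta: float = 0.026
    beta_sd: float = 0.027
    v_mm_s: float = 0.35
    cells_per_ml: float = 1e7
    cell_volume_um3: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        for name in ("beta_sd", "v_mm_s", "cells_per_ml", "cell_volume_um3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def cells_per_mm3(self) -> float:
        return self.cells_per_ml / 1000.0  # 1 ml = 1000 mm³

    @property
    def cell_volume_mm3(self) -> float:
        return self.cell_volume_um3 * 1e-9

    def width_slope_mm_per_h(self, beta: float | None = None) -> float:
        """dW/dt = 2 beta v C V / pi, in mm per hour."""
        b = self.beta if beta is None else beta
        v_mm_h = self.v_mm_s * SECONDS_PER_HOUR
        return 2.0 * b * v_mm_h * self.cells_per_mm3 * self.cell_volume_mm3 / np.pi


def predict_width(p: FiltrationParams, t_h):
    """Forward model W(t) with uncertainty band.

    Parameters
    ----------
    t_h : scalar or array of times in hours (>= 0).

    Returns
    -------
    (W, W_low, W_high) in mm; the band evaluates beta ± beta_sd, clipped at 0.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    w = p.width_slope_mm_per_h() * t
    lo = p.width_slope_mm_per_h(max(p.beta - p.beta_sd, 0.0)) * t
    hi = p.width_slope_mm_per_h(p.beta + p.beta_sd) * t
    return w, lo, hi


@dataclass(frozen=True)
class FiltrationResults:
    """Per-streamer and population estimates of the filtration efficiency."""

    beta: float
    beta_sd: float
    per_streamer: np.ndarray
    params: FiltrationParams
    n_streamers: int
    window_end_h: float

    def predict(self, t_h):
        """Model band at the estimated beta ± sd."""
        p = FiltrationParams(
            beta=self.beta,
            beta_sd=self.beta_sd,
            v_mm_s=self.params.v_mm_s,
            cells_per_ml=self.params.cells_per_ml,
            cell_volume_um3=self.params.cell_volume_um3,
        )
        return predict_width(p, t_h)

    def summary(self) -> str:
        return (
            "Streamer filtration model  W(t) = 2 beta v C V t / pi\n"
            f"  streamers fitted : {self.n_streamers}\n"
            f"  fit window       : t <= {self.window_end_h:g} h\n"
            f"  v = {self.params.v_mm_s:g} mm/s, C = {self.params.cells_per_ml:.3g} "
            f"cells/ml, V = {self.params.cell_volume_um3:g} um3\n"
            f"  beta = {self.beta:.4g} +/- {self.beta_sd:.4g}"
        )


class StreamerFiltrationModel:
    """Estimate beta from one or more observed width series.

    Each series is a ``(t_h, W_mm)`` pair of equal-length arrays.  Per
    streamer, beta is the slope of the through-origin least-squares fit of
    W against t inside the pre-plateau window, divided by ``2 v C V / pi``.
    The population estimate is the mean ± sd over streamers.
    """

    def __init__(
        self,
        series: Sequence[tuple],
        params: FiltrationParams | None = None,
        window_end_h: float = 70.0,
    ):
        if params is None:
            params = FiltrationParams()
        if params.v_mm_s <= 0 or params.cells_per_ml <= 0 or params.cell_volume_um3 <= 0:
            raise ValueError("v, C and V must be positive to invert the model")
        self.series = [(np.asarray(t, float), np.asarray(w, float)) for t, w in series]
        self.params = params
        self.window_end_h = float(window_end_h)

    def fit(self) -> FiltrationResults:
        unit_slope = self.params.width_slope_mm_per_h(beta=1.0)
        betas = []
        for t, w in self.series:
            sel = (t <= self.window_end_h) & (t >= 0)
            t_w, w_w = t[sel], w[sel]
            if t_w.size < 3:
                raise ValueError(
                    f"need >= 3 points in the fitting window (t <= {self.window_end_h} h); "
                    f"got {t_w.size}"
                )
            denom = float(np.sum(t_w**2))
            slope = float(np.sum(t_w * w_w)) / denom if denom > 0 else 0.0
            betas.append(slope / unit_slope)
        betas = np.asarray(betas)
        sd = float(np.std(betas, ddof=1)) if betas.size > 1 else 0.0
        return FiltrationResults(
            beta=float(np.mean(betas)),
            beta_sd=sd,
            per_streamer=betas,
            params=self.params,
            n_streamers=len(betas),
            window_end_h=self.window_end_h,
        )


def estimate_beta(
    series: Sequence[tuple],
    params: FiltrationParams | None = None,
    window_end_h: float = 70.0,
) -> tuple[float, float]:
    """Functional wrapper: population (beta, beta_sd) from width series."""
    res = StreamerFiltrationModel(series, params=params, window_end_h=window_end_h).fit()
    return res.beta, res.beta_sd
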