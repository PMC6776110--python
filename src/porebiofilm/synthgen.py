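"""Synthetic porous-device geometries, time-lapse stacks, and OTU tables.

Every downstream stage of the quantification pipeline is testable against
known ground truth generated here.  The forward model mimics the imaging
experiment: a planar device packed with circular grains, transmitted-light
frames recorded hourly, biofilm appearing as darkening against a bright
background.

The rendered biology:

* an annular *base biofilm* (BB) whose mean thickness follows a logistic
  curve; before the film closes, colonisation is patchy (random arcs whose
  total angular fraction tracks the logistic); after closure the boundary
  roughens into sinusoidal fingers; from a set onset time, thickness in a
  downstream angular sector is suppressed (the oxygen-limitation gap);
* two *streamers* per grain, rendered as flow-aligned lobes with an
  elliptical tip, whose width grows linearly at the colloid-filtration rate
  ``2 beta v C V / pi`` until a plateau and whose length rises, overshoots,
  and relaxes to an equilibrium; internal speckle (punched holes with a
  per-streamer frozen pattern) controls streamer porosity.

Ground truth (analytic thickness profiles, tortuosity, areas, per-streamer
L/W/porosity) is recorded per frame from the same quantities used to
render, so mask-derived truth and rendered rasters agree by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filtration import FiltrationParams

__all__ = [
    "Grain",
    "DeviceGeometry",
    "GrowthScenario",
    "GroundTruth",
    "SyntheticOTUSpec",
    "generate_geometry",
    "simulate_timelapse",
    "simulate_otu_tables",
    "desk_geometry",
    "desk_scenario",
]

N_ANGLE_BINS = 3600  # 0.1 degree resolution
MAX_RASTER_PIXELS = 30_000_000


@dataclass(frozen=True)
class Grain:
    grain_id: int
    x_mm: float
    y_mm: float
    radius_mm: float


@dataclass(frozen=True)
class DeviceGeometry:
    """Porous-device layout: rectangular domain plus circular grains.

    Physical coordinates are mm with x along the flow (+x downstream) and y
    upward; raster row 0 is the top of the domain.  ``pixel_size_um`` sets
    the rendering resolution.
    """

    domain_width_mm: float
    domain_height_mm: float
    pixel_size_um: float
    grains: tuple[Grain, ...]
    flow_direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for g in self.grains:
            if g.radius_mm <= 0 or g.radius_mm >= self.domain_width_mm / 2:
                raise ValueError(f"grain {g.grain_id}: radius out of range")
            if not (
                g.radius_mm <= g.x_mm <= self.domain_width_mm - g.radius_mm
                and g.radius_mm <= g.y_mm <= self.domain_height_mm - g.radius_mm
            ):
                raise ValueError(f"grain {g.grain_id} extends outside the domain")
        for i, a in enumerate(self.grains):
            for b in self.grains[i + 1 :]:
                d = np.hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm)
                if d < a.radius_mm + b.radius_mm:
                    raise ValueError(f"grains {a.grain_id} and {b.grain_id} overlap")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered raster."""
        return (
            int(round(self.domain_height_mm / self.pixel_size_mm)),
            int(round(self.domain_width_mm / self.pixel_size_mm)),
        )

    def grain_center_px(self, g: Grain) -> tuple[float, float]:
        """(row, col) of a grain center; y is flipped (row 0 = top = y max)."""
        col = g.x_mm / self.pixel_size_mm - 0.5
        row = (self.domain_height_mm - g.y_mm) / self.pixel_size_mm - 0.5
        return row, col

    def grain_mask(self, dilate_px: float = 0.0) -> np.ndarray:
        """Boolean raster of all grain interiors (optionally dilated)."""
        h, w = self.shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        out = np.zeros((h, w), dtype=bool)
        for g in self.grains:
            cr, cc = self.grain_center_px(g)
            r_px = g.radius_mm / self.pixel_size_mm + dilate_px
            lo_r = max(int(cr - r_px) - 1, 0)
            hi_r = min(int(cr + r_px) + 2, h)
            lo_c = max(int(cc - r_px) - 1, 0)
            hi_c = min(int(cc + r_px) + 2, w)
            rr = rows[lo_r:hi_r] - cr
            cc_ = cols[:, lo_c:hi_c] - cc
            out[lo_r:hi_r, lo_c:hi_c] |= rr**2 + cc_**2 <= r_px**2
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.grain_id, g.x_mm, g.y_mm, g.radius_mm) for g in self.grains],
            columns=["id", "x_mm", "y_mm", "radius_mm"],
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, domain_mm: tuple[float, float], pixel_size_um: float
    ) -> "DeviceGeometry":
        grains = tuple(
            Grain(int(r.id), float(r.x_mm), float(r.y_mm), float(r.radius_mm))
            for r in df.itertuples()
        )
        return cls(domain_mm[0], domain_mm[1], pixel_size_um, grains)


def generate_geometry(
    n_grains: int,
    diameter_mean_mm: float = 0.9,
    diameter_sd_mm: float = 0.25,
    diameter_bounds_mm: tuple[float, float] = (0.4, 1.4),
    domain_mm: tuple[float, float] = (20.0, 20.0),
    pixel_size_um: float = 1.01,
    clearance_mm: float = 0.1,
    seed: int | None = None,
    max_tries: int = 20000,
) -> DeviceGeometry:
    """Random grain packing with truncated-Gaussian diameters.

    Diameters are rejection-sampled from N(mean, sd) within bounds; grains
    are placed by dart-throwing with a minimum surface-to-surface clearance
    (so pore throats exist).  Deterministic for a fixed seed.
    """
    lo, hi = diameter_bounds_mm
    area_budget = n_grains * np.pi * (diameter_mean_mm / 2) ** 2
    if area_budget >= 0.6 * domain_mm[0] * domain_mm[1]:
        raise ValueError("infeasible packing: grains would exceed 60% of the domain")
    rng = np.random.default_rng(seed)

    def draw_diameter():
        for _ in range(1000):
            d = rng.normal(diameter_mean_mm, diameter_sd_mm)
            if lo <= d <= hi:
                return d
        raise RuntimeError("diameter rejection sampling failed; check bounds")

    placed: list[Grain] = []
    tries = 0
    while len(placed) < n_grains:
        if tries >= max_tries:
            raise RuntimeError(
                f"dart-throwing placed only {len(placed)} of {n_grains} grains "
                f"after {max_tries} tries"
            )
        tries += 1
        r = draw_diameter() / 2.0
        x = rng.uniform(r, domain_mm[0] - r)
        y = rng.uniform(r, domain_mm[1] - r)
        ok = all(
            np.hypot(x - g.x_mm, y - g.y_mm) >= r + g.radius_mm + clearance_mm
            for g in placed
        )
        if ok:
            placed.append(Grain(len(placed), x, y, r))
    return DeviceGeometry(domain_mm[0], domain_mm[1], pixel_size_um, tuple(placed))


@dataclass(frozen=True)
class GrowthScenario:
    """Parameters of the rendered growth dynamics.

    BB thickness (µm) follows logistic(bb_K, bb_r, bb_t0); fingers modulate
    the closed film by ``1 + finger_amplitude * sin(finger_count * theta)``;
    from ``gap_onset_h`` on, thickness within ``±gap_halfwidth_deg`` of the
    downstream pole is multiplied by ``gap_suppression``.  Streamer width
    grows at the filtration-model rate for ``streamer_beta`` (with the
    scenario's v, C, V) until ``streamer_plateau_w_mm``; length rises
    linearly to ``streamer_l_peak_mm`` at ``streamer_t_peak_h``, relaxes to
    ``streamer_l_eq_mm`` by ``streamer_t_eq_h``, then holds.
    """

    bb_K_um: float = 50.0
    bb_r_per_h: float = float(np.log(2) / 6.5)  # doubling time 6.5 h
    bb_t0_h: float = 66.0
    closure_thickness_um: float = 5.0
    finger_amplitude: float = 0.12
    finger_count: int = 8
    gap_onset_h: float = 70.0
    gap_halfwidth_deg: float = 20.0
    gap_suppression: float = 0.15
    streamer_beta: float = 0.026
    streamer_plateau_w_mm: float = 0.04
    streamer_l_peak_mm: float = 1.2
    streamer_l_eq_mm: float = 0.59
    streamer_t_start_h: float = 30.0
    streamer_t_peak_h: float = 70.0
    streamer_t_eq_h: float = 120.0
    streamer_angle_deg: float = 25.0
    streamer_fill: float = 0.6
    v_mm_s: float = 0.35
    cells_per_ml: float = 1e7
    cell_volume_um3: float = 1.0
    frame_interval_h: float = 10.0
    n_frames: int = 23
    noise_sd: float = 2.0
    background_level: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 <= self.gap_halfwidth_deg < 180:
            raise ValueError("gap_halfwidth_deg must be in [0, 180)")
        for name in (
            "bb_K_um", "bb_r_per_h", "closure_thickness_um", "streamer_plateau_w_mm",
            "streamer_l_peak_mm", "streamer_l_eq_mm", "frame_interval_h", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h

    def width_slope_mm_per_h(self) -> float:
        return FiltrationParams(
            beta=self.streamer_beta, beta_sd=0.0, v_mm_s=self.v_mm_s,
            cells_per_ml=self.cells_per_ml, cell_volume_um3=self.cell_volume_um3,
        ).width_slope_mm_per_h()

    def bb_mean_thickness_um(self, t_h: float) -> float:
        return self.bb_K_um / (1.0 + np.exp(-self.bb_r_per_h * (t_h - self.bb_t0_h)))

    def streamer_length_mm(self, t_h: float) -> float:
        s = self
        if t_h <= s.streamer_t_start_h:
            return 0.0
        if t_h <= s.streamer_t_peak_h:
            f = (t_h - s.streamer_t_start_h) / (s.streamer_t_peak_h - s.streamer_t_start_h)
            return f * s.streamer_l_peak_mm
        if t_h <= s.streamer_t_eq_h:
            f = (t_h - s.streamer_t_peak_h) / (s.streamer_t_eq_h - s.streamer_t_peak_h)
            return s.streamer_l_peak_mm + f * (s.streamer_l_eq_mm - s.streamer_l_peak_mm)
        return s.streamer_l_eq_mm

    def streamer_width_mm(self, t_h: float) -> float:
        return min(self.width_slope_mm_per_h() * t_h, self.streamer_plateau_w_mm)


@dataclass
class GroundTruth:
    """Per-frame truth recorded during rendering.

    ``thickness_profiles[f, g]`` is the analytic BB thickness (µm) of grain
    ``g`` at frame ``f`` in 3600 bins of 0.1° (bin 0 at the downstream pole,
    counterclockwise).  ``bb`` and ``streamers`` are tidy tables of the
    scalar truths; ``biomass`` holds the noise-free rendered masks.
    """

    times_h: np.ndarray
    thickness_profiles: np.ndarray  # (n_frames, n_grains, 3600) µm
    bb: pd.DataFrame  # frame, time_h, grain_id, tortuosity, area_mm2, closed
    streamers: pd.DataFrame  # frame, time_h, grain_id, side, L_mm, W_mm, porosity, area_mm2
    biomass: np.ndarray  # (n_frames, H, W) bool: rendered biomass (BB + streamers)
    bb_masks: np.ndarray  # (n_frames, H, W) bool: rendered BB layer only


def _truth_profile(
    scenario: GrowthScenario, t_h: float, phase: float, arc_centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic thickness profile (µm) over 3600 bins for one grain.

    Returns ``(profile, unsuppressed)``: the second omits the downstream-gap
    suppression, so the gap's biomass deficit can be integrated exactly.
    """
    s = scenario
    theta = (np.arange(N_ANGLE_BINS) + 0.5) * (2 * np.pi / N_ANGLE_BINS)
    hbar = s.bb_mean_thickness_um(t_h)
    if hbar <= 0:
        return np.zeros(N_ANGLE_BINS)
    if hbar >= s.closure_thickness_um:
        h = hbar * (1.0 + s.finger_amplitude * np.sin(s.finger_count * theta + phase))
    else:
        # patchy arc colonisation: evenly spaced arcs (random per-grain
        # rotation) whose union covers exactly the fraction h/closure, so
        # the film closes continuously as the fraction reaches 1
        frac = hbar / s.closure_thickness_um
        h = np.zeros(N_ANGLE_BINS)
        halfwidth = frac * np.pi / max(len(arc_centers), 1)
        for c in arc_centers:
            d = np.abs((theta - c + np.pi) % (2 * np.pi) - np.pi)
            h[d <= halfwidth] = s.closure_thickness_um
    h_unsup = h.copy()
    if t_h >= s.gap_onset_h and s.gap_halfwidth_deg > 0:
        d_deg = np.abs((np.degrees(theta) + 180.0) % 360.0 - 180.0)
        h[d_deg <= s.gap_halfwidth_deg] *= s.gap_suppression
    return h, h_unsup


def _tortuosity_of_profile(h_um: np.ndarray, radius_mm: float) -> tuple[float, bool]:
    """Analytic tortuosity of the outer boundary rho = r + h(theta).

    Closed film: arc length of the polar curve over 2*pi(r + mean h).
    Open film: sum of outer-arc lengths over the grain perimeter (< 1).
    """
    dtheta = 2 * np.pi / N_ANGLE_BINS
    rho = radius_mm + h_um / 1000.0
    closed = bool(np.all(h_um > 0))
    if closed:
        drho = np.gradient(rho, dtheta)
        perim = float(np.sum(np.sqrt(rho**2 + drho**2)) * dtheta)
        ref = 2 * np.pi * (radius_mm + float(np.mean(h_um)) / 1000.0)
        return perim / ref, True
    covered = h_um > 0
    perim = float(np.sum(rho[covered]) * dtheta)
    return perim / (2 * np.pi * radius_mm), False


def _render_streamer(
    geom: DeviceGeometry,
    grain: Grain,
    attach_angle_rad: float,
    base_radius_mm: float,
    L_mm: float,
    W_mm: float,
    holes: np.ndarray,
    hole_radius_px: float,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rasterise one flow-aligned lobe; returns (biomass, footprint, truth).

    The lobe starts at the BB outer boundary at the attachment angle and
    extends along +x with constant half-width W/2, capped by an elliptical
    tip.  ``holes`` are (s, lateral) centers in px of the frozen speckle
    pattern; pixels within ``hole_radius_px`` of a hole are void.
    """
    h, w = geom.shape
    px = geom.pixel_size_mm
    cr, cc = geom.grain_center_px(grain)
    base_row = cr - (base_radius_mm / px) * np.sin(attach_angle_rad)
    base_col = cc + (base_radius_mm / px) * np.cos(attach_angle_rad)
    L_px = L_mm / px
    Whalf_px = max(W_mm / (2 * px), 0.5)
    lo_r = max(int(base_row - Whalf_px) - 2, 0)
    hi_r = min(int(base_row + Whalf_px) + 3, h)
    lo_c = max(int(base_col) - 1, 0)
    hi_c = min(int(base_col + L_px) + 3, w)
    empty = np.zeros((h, w), dtype=bool)
    if lo_r >= hi_r or lo_c >= hi_c or L_px < 1:
        return empty, empty, {"L_mm": 0.0, "W_mm": 0.0, "porosity": 0.0, "area_mm2": 0.0}
    rows = np.arange(lo_r, hi_r)[:, None] - base_row
    cols = np.arange(lo_c, hi_c)[None, :] - base_col
    s = np.broadcast_to(cols, (hi_r - lo_r, hi_c - lo_c))
    lat = np.broadcast_to(rows, (hi_r - lo_r, hi_c - lo_c))
    cap = min(2.0 * 2 * Whalf_px, L_px / 2.0)
    half = np.where(
        s <= L_px - cap,
        Whalf_px,
        Whalf_px * np.sqrt(np.clip(1 - ((s - (L_px - cap)) / cap) ** 2, 0, 1)),
    )
    footprint_local = (s >= 0) & (s <= L_px) & (np.abs(lat) <= half)
    # clip to domain interior / outside all grains
    footprint = np.zeros((h, w), dtype=bool)
    footprint[lo_r:hi_r, lo_c:hi_c] = footprint_local
    # punch frozen holes; speckle is *internal*, so the envelope keeps an
    # intact rim and the boundary stays smooth
    biomass_local = footprint_local.copy()
    interior = footprint_local & (np.abs(lat) <= half - 2.5)
    if holes.size:
        hole_px = np.zeros_like(biomass_local)
        for hs, hl in holes:
            d2 = (s - hs) ** 2 + (lat - hl) ** 2
            hole_px |= d2 <= hole_radius_px**2
        biomass_local &= ~(hole_px & interior)
    biomass = np.zeros((h, w), dtype=bool)
    biomass[lo_r:hi_r, lo_c:hi_c] = biomass_local
    foot_n = int(footprint.sum())
    if foot_n == 0:
        return empty, empty, {"L_mm": 0.0, "W_mm": 0.0, "porosity": 0.0, "area_mm2": 0.0}
    # truth from the rendered footprint
    s_occ = s[footprint_local]
    s_min, s_max = float(s_occ.min()), float(s_occ.max())
    ss = np.linspace(max(s_min, 0), s_max, 200)
    half_prof = np.where(
        ss <= L_px - cap, Whalf_px,
        Whalf_px * np.sqrt(np.clip(1 - ((ss - (L_px - cap)) / cap) ** 2, 0, 1)),
    )
    truth = {
        "L_mm": (s_max - s_min + 1) * px,
        "W_mm": float(np.mean(2 * half_prof)) * px,
        "porosity": float(biomass.sum() / foot_n),
        "area_mm2": float(biomass.sum()) * px**2,
    }
    return biomass, footprint, truth


def simulate_timelapse(
    geom: DeviceGeometry, scenario: GrowthScenario
) -> tuple[np.ndarray, GroundTruth]:
    """Render the time-lapse stack and record ground truth.

    Returns
    -------
    stack : uint8 array (n_frames, H, W); frame 0 is biofilm-free background.
    truth : :class:`GroundTruth`
    """
    h, w = geom.shape
    if h * w > MAX_RASTER_PIXELS:
        raise ValueError(
            f"raster {h}x{w} exceeds the {MAX_RASTER_PIXELS}-pixel guard; "
            "use a coarser pixel size or a sub-domain"
        )
    s = scenario
    px = geom.pixel_size_mm
    rng = np.random.default_rng(s.seed)
    n_grains = len(geom.grains)

    # frozen per-grain randomness: finger phase, patchy-arc centers
    phases = rng.uniform(0, 2 * np.pi, size=n_grains)
    n_arcs = max(s.finger_count, 1)
    arc_centers = [
        (np.arange(n_arcs) * 2 * np.pi / n_arcs + rng.uniform(0, 2 * np.pi))
        % (2 * np.pi)
        for _ in range(n_grains)
    ]
    # frozen per-streamer speckle hole patterns
    hole_radius_px = 2.0
    fill = min(max(s.streamer_fill, 1e-3), 1.0)
    lam = -np.log(fill) / (np.pi * hole_radius_px**2)  # Boolean-model density
    max_L_px = s.streamer_l_peak_mm / px
    max_Wpx = s.streamer_plateau_w_mm / px
    holes = {}
    for gi in range(n_grains):
        for side in (+1, -1):
            n_holes = rng.poisson(lam * max_L_px * (max_Wpx + 4))
            hs = rng.uniform(0, max_L_px, size=n_holes)
            hl = rng.uniform(-(max_Wpx / 2 + 2), max_Wpx / 2 + 2, size=n_holes)
            holes[(gi, side)] = np.column_stack([hs, hl]) if n_holes else np.empty((0, 2))

    # static background: bright field, mild fixed illumination gradient, grains darker
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    background = s.background_level + 10.0 * np.sin(2 * np.pi * cols / max(w, 1))
    background = np.broadcast_to(background, (h, w)).copy()
    grain_interior = geom.grain_mask()
    grain_occluded = geom.grain_mask(dilate_px=1.0)
    background[grain_interior] = s.background_level * 0.85

    # per-grain pixel geometry (bounding boxes around the largest possible BB)
    grain_geo = []
    for g in geom.grains:
        cr, cc = geom.grain_center_px(g)
        r_px = g.radius_mm / px
        reach = r_px + (s.bb_K_um * (1 + s.finger_amplitude) * 1.2) / geom.pixel_size_um + 2
        lo_r = max(int(cr - reach), 0)
        hi_r = min(int(cr + reach) + 1, h)
        lo_c = max(int(cc - reach), 0)
        hi_c = min(int(cc + reach) + 1, w)
        dy = -(rows[lo_r:hi_r] - cr)  # physical y is up
        dx = cols[:, lo_c:hi_c] - cc
        dist = np.sqrt(dx**2 + dy**2)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        bins = np.minimum((theta / (2 * np.pi) * N_ANGLE_BINS).astype(int), N_ANGLE_BINS - 1)
        grain_geo.append((slice(lo_r, hi_r), slice(lo_c, hi_c), dist, bins, r_px))

    times = s.times_h
    stack = np.empty((s.n_frames, h, w), dtype=np.uint8)
    profiles = np.zeros((s.n_frames, n_grains, N_ANGLE_BINS))
    bb_rows, str_rows = [], []
    biomass_all = np.zeros((s.n_frames, h, w), dtype=bool)
    bb_all = np.zeros((s.n_frames, h, w), dtype=bool)

    for f, t in enumerate(times):
        atten = np.zeros((h, w))
        frame_bb = np.zeros((h, w), dtype=bool)
        frame_biomass = np.zeros((h, w), dtype=bool)
        if f > 0:
            for gi, g in enumerate(geom.grains):
                prof, prof_unsup = _truth_profile(s, t, phases[gi], arc_centers[gi])
                profiles[f, gi] = prof
                dtheta = 2 * np.pi / N_ANGLE_BINS
                gap_missing = float(np.sum(
                    0.5 * ((g.radius_mm + prof_unsup / 1000.0) ** 2
                           - (g.radius_mm + prof / 1000.0) ** 2) * dtheta
                ))
                sl_r, sl_c, dist, bins, r_px = grain_geo[gi]
                h_px = prof[bins] / geom.pixel_size_um
                # the first pixel ring hugging the grain edge is occluded by
                # the pillar wall in transmitted light; biomass renders outside it
                local_bb = (dist > r_px + 1) & (dist <= r_px + h_px)
                frame_bb[sl_r, sl_c] |= local_bb
                # darker in proportion to local radial thickness
                a = 60.0 + 60.0 * np.minimum(prof[bins] / max(s.bb_K_um, 1e-9), 1.0)
                atten[sl_r, sl_c] = np.where(local_bb, np.maximum(atten[sl_r, sl_c], a), atten[sl_r, sl_c])
                tort, closed = _tortuosity_of_profile(prof, g.radius_mm)
                bb_rows.append(
                    (f, t, g.grain_id, tort, float(local_bb.sum()) * px**2, closed,
                     gap_missing)
                )
                # streamers
                L = s.streamer_length_mm(t)
                W = s.streamer_width_mm(t)
                if L > 0 and W > 0:
                    for side in (+1, -1):
                        ang = np.radians(side * s.streamer_angle_deg)
                        bin_at = int(np.mod(ang, 2 * np.pi) / (2 * np.pi) * N_ANGLE_BINS)
                        base_r = g.radius_mm + prof[bin_at] / 1000.0
                        bio, foot, tr = _render_streamer(
                            geom, g, ang, base_r, L, W,
                            holes[(gi, side)], hole_radius_px,
                        )
                        bio &= ~grain_occluded & ~frame_bb
                        foot &= ~grain_occluded & ~frame_bb
                        frame_biomass |= bio
                        aw = 60.0 + 60.0 * min(W * 1000.0 / max(s.bb_K_um, 1e-9), 1.0)
                        atten[bio] = np.maximum(atten[bio], aw)
                        foot_n = int(foot.sum())
                        poros = float(bio.sum() / foot_n) if foot_n else 0.0
                        str_rows.append(
                            (f, t, g.grain_id, side, tr["L_mm"], tr["W_mm"],
                             poros, float(bio.sum()) * px**2)
                        )
            frame_biomass |= frame_bb
        img = background - np.minimum(atten, 180.0)
        if s.noise_sd > 0:
            img = img + rng.normal(0.0, s.noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 255).astype(np.uint8)
        biomass_all[f] = frame_biomass
        bb_all[f] = frame_bb

    truth = GroundTruth(
        times_h=times,
        thickness_profiles=profiles,
        bb=pd.DataFrame(
            bb_rows,
            columns=["frame", "time_h", "grain_id", "tortuosity", "area_mm2",
                     "closed", "gap_missing_mm2"],
        ),
        streamers=pd.DataFrame(
            str_rows,
            columns=["frame", "time_h", "grain_id", "side", "L_mm", "W_mm", "porosity", "area_mm2"],
        ),
        biomass=biomass_all,
        bb_masks=bb_all,
    )
    return stack, truth


def desk_geometry(pixel_size_um: float = 5.0) -> DeviceGeometry:
    """Default desk-scale layout: 2x2 mm, 4 grains in an upstream column.

    Grains sit near the inflow edge so every streamer has free downstream
    pore space; this keeps the full streamer length envelope renderable in a
    small raster.
    """
    grains = tuple(
        Grain(i, 0.45, 0.25 + 0.5 * i, 0.15) for i in range(4)
    )
    return DeviceGeometry(2.0, 2.0, pixel_size_um, grains)


def desk_scenario(**overrides) -> GrowthScenario:
    """Default desk-scale growth scenario (23 hourly-decimated frames, 220 h)."""
    return replace(GrowthScenario(), **overrides) if overrides else GrowthScenario()


@dataclass(frozen=True)
class SyntheticOTUSpec:
    """Specification of the synthetic three-sample OTU table.

    A lognormal core community is shared by inoculum, BB, and streamer;
    architecture-specific OTUs appear only in their sample, at low relative
    abundance (rare tails).  Counts are multinomial draws at the stated
    sequencing depth.
    """

    n_core_otus: int = 206
    n_unique_bb: int = 85
    n_unique_streamer: int = 136
    core_lognormal_mu: float = 0.0
    core_lognormal_sigma: float = 2.0
    unique_mean_reads: float = 3.0
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        for name in ("n_core_otus", "n_unique_bb", "n_unique_streamer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def simulate_otu_tables(spec: SyntheticOTUSpec) -> pd.DataFrame:
    """Draw the inoculum/BB/streamer OTU table from the spec's profiles.

    Returns a DataFrame (rows = OTU ids, columns = samples).  The expected
    read count of each architecture-specific OTU is ``unique_mean_reads``;
    shared-core relative abundances are identical across samples, so
    community differences come only from the rare tails and sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    core = rng.lognormal(spec.core_lognormal_mu, spec.core_lognormal_sigma, spec.n_core_otus)
    core_p = core / core.sum()
    tail_p = spec.unique_mean_reads / spec.depth

    n_total = spec.n_core_otus + spec.n_unique_bb + spec.n_unique_streamer
    ids = (
        [f"OTU_core_{i:04d}" for i in range(spec.n_core_otus)]
        + [f"OTU_bb_{i:04d}" for i in range(spec.n_unique_bb)]
        + [f"OTU_str_{i:04d}" for i in range(spec.n_unique_streamer)]
    )

    def profile(unique_bb: bool, unique_str: bool) -> np.ndarray:
        p = np.zeros(n_total)
        tail_mass = (spec.n_unique_bb * tail_p if unique_bb else 0.0) + (
            spec.n_unique_streamer * tail_p if unique_str else 0.0
        )
        p[: spec.n_core_otus] = core_p * (1.0 - tail_mass)
        if unique_bb:
            p[spec.n_core_otus : spec.n_core_otus + spec.n_unique_bb] = tail_p
        if unique_str:
            p[spec.n_core_otus + spec.n_unique_bb :] = tail_p
        return p

    cols = {
        "inoculum": rng.multinomial(spec.depth, profile(False, False)),
        "BB": rng.multinomial(spec.depth, profile(True, False)),
        "streamer": rng.multinomial(spec.depth, profile(False, True)),
    }
    return pd.DataFrame(cols, index=ids)
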