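"""Partition biomass into base biofilm and streamers; morphometrics.

The base biofilm (BB) of a grain is the biomass inside the largest radius
reachable by a consecutive run of concentric annuli, starting at the grain
surface, in which at least 35% of each annulus is biomass-covered.  What
remains after BB removal is clustered into streamers: connected components
closer than 45 µm (boundary to boundary) are merged into one streamer and
assigned to the nearest upstream grain.

Metrics follow the conventions of quantitative biofilm image analysis:

* thickness profile: radial extent of BB along 3600 rays (0.1° steps),
  angle 0 at the downstream pole, counterclockwise;
* P_BB and tortuosity: length of the external BB boundary polygon over a
  reference perimeter (see :func:`bb_perimeter_and_tortuosity`);
* streamer length L: geodesic diameter of the skeleton graph of the
  (morphologically closed) streamer, end-corrected by the boundary EDT;
* streamer width W: twice the mean EDT over skeleton pixels;
* porosity: biomass fraction inside the closed streamer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .imgcore import remove_small_components
from .synthgen import DeviceGeometry, Grain, N_ANGLE_BINS

__all__ = [
    "BBClassification",
    "StreamerSet",
    "classify_bb",
    "angular_thickness",
    "bb_perimeter_and_tortuosity",
    "delineate_streamers",
    "streamer_length",
    "streamer_width",
    "streamer_porosity",
    "coverage_series",
    "quantify_stack",
]

COVERAGE_THRESHOLD = 0.35
RING_STEP_UM = 10.0
LINK_DISTANCE_UM = 45.0
MAX_BB_REACH_UM = 500.0


# ---------------------------------------------------------------- BB layer


@dataclass(frozen=True)
class BBClassification:
    """Result of the ring rule on one frame."""

    bb_mask: np.ndarray  # biomass within each grain's BB radius
    outer_radius_mm: dict  # grain_id -> BB outer radius (= grain radius if none)
    per_grain_masks: dict  # grain_id -> boolean raster of that grain's BB


def _grain_pixel_frame(geometry: DeviceGeometry, grain: Grain, reach_px: float):
    """Distance/angle rasters in a bounding box around one grain."""
    h, w = geometry.shape
    cr, cc = geometry.grain_center_px(grain)
    r_px = grain.radius_mm / geometry.pixel_size_mm
    lo_r = max(int(cr - r_px - reach_px) - 1, 0)
    hi_r = min(int(cr + r_px + reach_px) + 2, h)
    lo_c = max(int(cc - r_px - reach_px) - 1, 0)
    hi_c = min(int(cc + r_px + reach_px) + 2, w)
    dy = -(np.arange(lo_r, hi_r)[:, None] - cr)  # physical y up
    dx = np.arange(lo_c, hi_c)[None, :] - cc
    dist = np.sqrt(dx**2 + dy**2)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    return (slice(lo_r, hi_r), slice(lo_c, hi_c)), dist, theta, r_px, (cr, cc)


def classify_bb(
    mask: np.ndarray,
    geometry: DeviceGeometry,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    ring_step_um: float = RING_STEP_UM,
    max_reach_um: float = MAX_BB_REACH_UM,
) -> BBClassification:
    """Apply the ≥35% consecutive-annulus rule to one biomass mask.

    Ring coverage is inclusive (a ring at exactly the threshold counts) and
    computed over in-domain ring pixels outside all grains.  A grain whose
    first ring fails has no BB (outer radius = grain radius).
    """
    px_mm = geometry.pixel_size_mm
    step_px = ring_step_um / geometry.pixel_size_um
    reach_px = max_reach_um / geometry.pixel_size_um
    all_grains = geometry.grain_mask()
    bb_mask = np.zeros_like(mask, dtype=bool)
    outer, per_grain = {}, {}
    for g in geometry.grains:
        (sl_r, sl_c), dist, _, r_px, _ = _grain_pixel_frame(geometry, g, reach_px)
        local_mask = mask[sl_r, sl_c]
        local_free = ~all_grains[sl_r, sl_c]
        n_rings = int(reach_px / step_px)
        run = 0
        for k in range(n_rings):
            ring = (dist > r_px + k * step_px) & (dist <= r_px + (k + 1) * step_px) & local_free
            n_ring = int(ring.sum())
            if n_ring == 0:
                break
            if local_mask[ring].sum() / n_ring >= coverage_threshold:
                run = k + 1
            else:
                break
        R_px = r_px + run * step_px
        gm = np.zeros_like(mask, dtype=bool)
        if run > 0:
            gm[sl_r, sl_c] = local_mask & (dist > r_px) & (dist <= R_px) & local_free
        per_grain[g.grain_id] = gm
        bb_mask |= gm
        outer[g.grain_id] = R_px * px_mm
    return BBClassification(bb_mask=bb_mask, outer_radius_mm=outer, per_grain_masks=per_grain)


def angular_thickness(
    bb_mask: np.ndarray,
    geometry: DeviceGeometry,
    grain: Grain,
    angular_step_deg: float = 0.1,
    radial_step_px: float = 0.5,
    max_reach_um: float = MAX_BB_REACH_UM,
) -> np.ndarray:
    """Thickness (µm) along rays from the grain center.

    For each ray, thickness is the radius of the outermost BB sample in the
    run contiguous with the grain surface (single-sample gaps are bridged to
    absorb pixelation), minus the grain radius; 0 where the surface is bare.
    """
    n_bins = int(round(360.0 / angular_step_deg))
    h, w = bb_mask.shape
    cr, cc = geometry.grain_center_px(grain)
    r_px = grain.radius_mm / geometry.pixel_size_mm
    reach_px = max_reach_um / geometry.pixel_size_um
    theta = (np.arange(n_bins) + 0.5) * (2 * np.pi / n_bins)
    radii = np.arange(r_px + radial_step_px / 2, r_px + reach_px, radial_step_px)
    if radii.size == 0:
        return np.zeros(n_bins)
    rows = cr - radii[None, :] * np.sin(theta)[:, None]
    cols = cc + radii[None, :] * np.cos(theta)[:, None]
    rr = np.clip(np.round(rows).astype(int), 0, h - 1)
    cl = np.clip(np.round(cols).astype(int), 0, w - 1)
    inside = (rows >= -0.5) & (rows < h - 0.5) & (cols >= -0.5) & (cols < w - 0.5)
    samples = bb_mask[rr, cl] & inside
    # the run must start within a small clearance of the grain surface (the
    # pixel ring hugging the grain edge is excluded during segmentation)
    n_s = samples.shape[1]
    idx = np.arange(n_s)[None, :]
    first = np.where(samples.any(axis=1), np.argmax(samples, axis=1), n_s)
    surface_ok = radii[np.minimum(first, n_s - 1)] - r_px <= 2.5
    # end of the surface-contiguous run = first double-gap past the start
    false = ~samples
    double_gap = false[:, :-1] & false[:, 1:] & (idx[:, :-1] >= first[:, None])
    has_gap = double_gap.any(axis=1)
    end = np.where(has_gap, np.argmax(double_gap, axis=1), n_s - 1)
    in_run = samples & (idx >= first[:, None]) & (idx <= end[:, None])
    any_run = in_run.any(axis=1) & surface_ok
    last = np.where(any_run, samples.shape[1] - 1 - np.argmax(in_run[:, ::-1], axis=1), -1)
    thickness_px = np.where(any_run, radii[np.clip(last, 0, None)] + radial_step_px / 2 - r_px, 0.0)
    return thickness_px * geometry.pixel_size_um


def _smoothed_polygon_length(contour: np.ndarray, window: int = 5) -> float:
    """Length of a closed boundary polygon after circular moving-average
    smoothing (suppresses the staircase bias of marching squares)."""
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    n = len(pts)
    if n < 3:
        return 0.0
    w = min(window, n)
    kernel = np.ones(w) / w
    padded = np.vstack([pts[-w:], pts, pts[:w]])
    sm = np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="same")[w:-w] for i in range(2)]
    )
    closed = np.vstack([sm, sm[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


def bb_perimeter_and_tortuosity(
    bb_mask_grain: np.ndarray,
    geometry: DeviceGeometry,
    grain: Grain,
    thickness_profile_um: np.ndarray | None = None,
) -> tuple[float, float]:
    """(P_BB in mm, tortuosity) of one grain's BB.

    Closed film (every angular bin colonised): P_BB is the smoothed length
    of the external boundary of BB ∪ grain, and tortuosity normalises by the
    perimeter of the *expected smooth* outer circle, 2π(r + mean thickness) —
    so a smooth closed annulus scores 1 and fingering scores > 1.  Open
    film: P_BB sums the external boundaries of the BB arcs excluding
    grain-contact segments, normalised by the grain perimeter 2πr, which
    stays below 1 until the surface is fully colonised.
    """
    px_mm = geometry.pixel_size_mm
    if thickness_profile_um is None:
        thickness_profile_um = angular_thickness(bb_mask_grain, geometry, grain)
    closed = bool(np.all(thickness_profile_um > 0))
    cr, cc = geometry.grain_center_px(grain)
    r_px = grain.radius_mm / px_mm
    if not bb_mask_grain.any():
        return 0.0, 0.0
    if closed:
        h, w = bb_mask_grain.shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= r_px**2
        region = bb_mask_grain | disk
        contours = measure.find_contours(region.astype(float), 0.5)
        outer = max(contours, key=lambda c: len(c))
        p_mm = _smoothed_polygon_length(outer) * px_mm
        mean_h_mm = float(np.mean(thickness_profile_um)) / 1000.0
        return p_mm, p_mm / (2 * np.pi * (grain.radius_mm + mean_h_mm))
    # open arcs: drop boundary points touching the grain surface
    total = 0.0
    for contour in measure.find_contours(bb_mask_grain.astype(float), 0.5):
        d = np.hypot(contour[:, 0] - cr, contour[:, 1] - cc)
        keep = d > r_px + 1.5
        seg = np.hypot(*np.diff(contour, axis=0).T)
        both = keep[:-1] & keep[1:]
        total += float(np.sum(seg[both]))
    p_mm = total * px_mm
    return p_mm, p_mm / (2 * np.pi * grain.radius_mm)


# ---------------------------------------------------------------- streamers


@dataclass(frozen=True)
class StreamerSet:
    """Labelled streamers of one frame (labels start at 1)."""

    labels: np.ndarray  # int raster; 0 = background
    n_streamers: int
    anchor_grain: dict  # label -> grain_id (or None)
    member_counts: dict  # label -> number of merged raw clusters

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _pairwise_merge(labels: np.ndarray, n: int, link_px: float) -> list[set]:
    """Union-find groups of components with boundary gap < link_px pixels.

    The gap between two components is (min center-to-center pixel distance
    − 1) px: touching pixels are 1 px apart center-to-center but have zero
    boundary gap.
    """
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    objects = ndimage.find_objects(labels)
    pad = int(np.ceil(link_px)) + 2
    h, w = labels.shape
    for i in range(1, n + 1):
        sl = objects[i - 1]
        if sl is None:
            continue
        win = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)),
        )
        sub = labels[win]
        comp = sub == i
        if not comp.any():
            continue
        dt = ndimage.distance_transform_edt(~comp)
        for j in np.unique(sub):
            if j <= i:
                continue
            dmin = dt[sub == j].min()
            if (dmin - 1.0) < link_px:
                union(i, int(j))
    groups: dict[int, set] = {}
    for lab in range(1, n + 1):
        groups.setdefault(find(lab), set()).add(lab)
    return list(groups.values())


def delineate_streamers(
    non_bb_mask: np.ndarray,
    geometry: DeviceGeometry,
    link_distance_um: float = LINK_DISTANCE_UM,
    min_size: int = 16,
) -> StreamerSet:
    """Merge biomass clusters into streamers by the <45 µm linkage rule.

    Single-linkage and transitive: any chain of clusters with pairwise
    boundary gaps below the threshold is one streamer.  Components below
    ``min_size`` pixels are discarded first (same noise rule as
    segmentation; also sheds sub-threshold fringe fragments of the BB
    boundary).  Each streamer is anchored to the nearest grain whose
    downstream half-plane contains the streamer's upstream endpoint.
    """
    link_px = link_distance_um / geometry.pixel_size_um
    cleaned = remove_small_components(non_bb_mask, min_size)
    raw_labels, n_raw = ndimage.label(cleaned, structure=np.ones((3, 3), int))
    if n_raw == 0:
        return StreamerSet(np.zeros_like(raw_labels), 0, {}, {})
    groups = _pairwise_merge(raw_labels, n_raw, link_px)
    # order groups by centroid for stable labelling
    cent = ndimage.center_of_mass(cleaned, raw_labels, index=range(1, n_raw + 1))
    cent = np.asarray(cent)

    def group_key(g):
        idx = np.array(sorted(g)) - 1
        return tuple(cent[idx].mean(axis=0))

    groups.sort(key=group_key)
    out = np.zeros_like(raw_labels)
    anchors, members = {}, {}
    lut = np.zeros(n_raw + 1, dtype=int)
    for new_label, g in enumerate(groups, start=1):
        for raw in g:
            lut[raw] = new_label
        members[new_label] = len(g)
    out = lut[raw_labels]
    for new_label in range(1, len(groups) + 1):
        ys, xs = np.nonzero(out == new_label)
        up = np.argmin(xs)
        up_rc = (ys[up], xs[up])
        anchors[new_label] = _anchor_grain(geometry, up_rc)
    return StreamerSet(out, len(groups), anchors, members)


def _anchor_grain(geometry: DeviceGeometry, upstream_rc: tuple) -> int | None:
    """Nearest grain whose downstream half-plane holds the given pixel."""
    best, best_d = None, np.inf
    fallback, fb_d = None, np.inf
    for g in geometry.grains:
        cr, cc = geometry.grain_center_px(g)
        d = np.hypot(upstream_rc[0] - cr, upstream_rc[1] - cc)
        if d < fb_d:
            fallback, fb_d = g.grain_id, d
        if upstream_rc[1] >= cc and d < best_d:
            best, best_d = g.grain_id, d
    return best if best is not None else fallback


def _closed_mask(mask: np.ndarray, geometry: DeviceGeometry,
                 link_distance_um: float = LINK_DISTANCE_UM) -> np.ndarray:
    """Streamer 'boundary' region: morphological closing with a disk of
    radius link_distance/2, with remaining interior voids filled — internal
    speckle belongs inside the boundary."""
    r = max(int(round(link_distance_um / 2 / geometry.pixel_size_um)), 1)
    sl = ndimage.find_objects(mask.astype(int))[0]
    pad = r + 2
    h, w = mask.shape
    win = (
        slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)),
        slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)),
    )
    out = np.zeros_like(mask)
    closed = ndimage.binary_closing(mask[win], structure=morphology.disk(r))
    out[win] = ndimage.binary_fill_holes(closed)
    return out


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    ys, xs = np.nonzero(skeleton)
    nodes = set(zip(ys.tolist(), xs.tolist()))
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for y, x in nodes:
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (y + dy, x + dx)
            if nb in nodes:
                G.add_edge((y, x), nb, weight=float(np.hypot(dy, dx)))
    return G


def _graph_diameter(G: nx.Graph) -> tuple[float, tuple, tuple]:
    """Geodesic diameter by repeated double-sweep over components."""
    best = (0.0, None, None)
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        u = next(iter(comp))
        for _ in range(3):  # double sweep, iterated for near-tree robustness
            dist = nx.single_source_dijkstra_path_length(sub, u)
            v, d = max(dist.items(), key=lambda kv: kv[1])
            if d <= best[0] and v == u:
                break
            if d > best[0]:
                best = (d, u, v)
            u = v
    return best


def streamer_length(
    mask: np.ndarray, geometry: DeviceGeometry,
    link_distance_um: float = LINK_DISTANCE_UM,
) -> float:
    """Streamer length L (mm): end-corrected skeleton geodesic diameter.

    The mask is morphologically closed, skeletonised, and the longest
    shortest path through the 8-connected skeleton graph (weights 1/√2) is
    found by iterated double-sweep; the EDT of the closed mask at the two
    path ends is added to recover the half-width lost to thinning.
    """
    if not mask.any():
        raise ValueError("empty streamer mask")
    closed = _closed_mask(mask, geometry, link_distance_um)
    skel = morphology.skeletonize(closed)
    if not skel.any():
        return float(np.sqrt(mask.sum())) * geometry.pixel_size_mm
    G = _skeleton_graph(skel)
    d, u, v = _graph_diameter(G)
    edt = ndimage.distance_transform_edt(closed)
    end_correction = (edt[u] + edt[v]) if u is not None else 0.0
    return (d + end_correction) * geometry.pixel_size_mm


def streamer_width(
    mask: np.ndarray, geometry: DeviceGeometry,
    link_distance_um: float = LINK_DISTANCE_UM,
) -> float:
    """Streamer mean width W (mm): twice the mean EDT on skeleton pixels."""
    if not mask.any():
        raise ValueError("empty streamer mask")
    closed = _closed_mask(mask, geometry, link_distance_um)
    skel = morphology.skeletonize(closed)
    if not skel.any():
        return float(np.sqrt(mask.sum())) * geometry.pixel_size_mm
    edt = ndimage.distance_transform_edt(closed)
    return 2.0 * float(edt[skel].mean()) * geometry.pixel_size_mm


def streamer_porosity(
    mask: np.ndarray, geometry: DeviceGeometry,
    link_distance_um: float = LINK_DISTANCE_UM,
) -> tuple[float, float]:
    """(biomass_fraction, void_fraction) inside the closed streamer boundary.

    Both are returned: densely packed streamers have biomass_fraction near 1.
    """
    if not mask.any():
        raise ValueError("empty streamer mask")
    closed = _closed_mask(mask, geometry, link_distance_um)
    n = int(closed.sum())
    bf = float(mask.sum() / n) if n else 0.0
    return bf, 1.0 - bf


# ---------------------------------------------------------------- pipeline


def coverage_series(
    times_h: np.ndarray,
    bb_masks: list,
    streamer_masks: list,
    geometry: DeviceGeometry,
) -> pd.DataFrame:
    """TB/BB/streamer coverage as fractions of the pore (non-grain) area."""
    pore_px = int((~geometry.grain_mask()).sum())
    rows = []
    for t, bb, st in zip(times_h, bb_masks, streamer_masks):
        b = int(bb.sum()) / pore_px
        s = int(st.sum()) / pore_px
        rows.append((t, b + s, b, s))
    return pd.DataFrame(rows, columns=["time_h", "TB", "BB", "streamer"])


def quantify_stack(masks, geometry: DeviceGeometry, **kwargs):
    """Run the full architecture pipeline over a mask sequence.

    Parameters
    ----------
    masks : :class:`~porebiofilm.imgcore.BiomassMasks` or (t, H, W) bool array
        plus a ``times_h`` keyword in the array case.

    Returns
    -------
    dict with keys ``bb`` (per-grain table), ``profiles`` (t × grain × 3600
    thickness array, µm), ``streamers`` (per-streamer table), ``coverage``
    (coverage series table).
    """
    if hasattr(masks, "masks"):
        mask_arr, times = masks.masks, masks.times_h
    else:
        mask_arr = np.asarray(masks)
        times = kwargs.pop("times_h")
    n_frames = len(mask_arr)
    n_grains = len(geometry.grains)
    profiles = np.zeros((n_frames, n_grains, N_ANGLE_BINS))
    bb_rows, str_rows = [], []
    bb_list, st_list = [], []
    for f in range(n_frames):
        cls = classify_bb(mask_arr[f], geometry, **kwargs)
        for gi, g in enumerate(geometry.grains):
            gm = cls.per_grain_masks[g.grain_id]
            prof = angular_thickness(gm, geometry, g)
            profiles[f, gi] = prof
            p_mm, tort = bb_perimeter_and_tortuosity(gm, geometry, g, prof)
            bb_rows.append(
                (f, times[f], g.grain_id, cls.outer_radius_mm[g.grain_id],
                 float(prof.mean()), p_mm, tort,
                 float(gm.sum()) * geometry.pixel_size_mm**2)
            )
        non_bb = mask_arr[f] & ~cls.bb_mask
        streamers = delineate_streamers(non_bb, geometry)
        st_mask = streamers.labels > 0
        # sub-threshold fragments (ring-rule-clipped finger tips) are biomass
        # contiguous with the BB boundary: they rejoin BB for area accounting
        residual = non_bb & ~st_mask
        for lab in range(1, streamers.n_streamers + 1):
            sm = streamers.mask(lab)
            L = streamer_length(sm, geometry)
            W = streamer_width(sm, geometry)
            bf, vf = streamer_porosity(sm, geometry)
            str_rows.append(
                (f, times[f], lab, streamers.anchor_grain[lab], L, W, bf, vf,
                 float(sm.sum()) * geometry.pixel_size_mm**2,
                 streamers.member_counts[lab])
            )
        bb_list.append(cls.bb_mask | residual)
        st_list.append(st_mask)
    return {
        "bb": pd.DataFrame(
            bb_rows,
            columns=["frame", "time_h", "grain_id", "outer_radius_mm",
                     "mean_thickness_um", "P_BB_mm", "tortuosity", "area_mm2"],
        ),
        "profiles": profiles,
        "streamers": pd.DataFrame(
            str_rows,
            columns=["frame", "time_h", "streamer_id", "anchor_grain", "L_mm",
                     "W_mm", "biomass_fraction", "void_fraction", "area_mm2",
                     "n_members"],
        ),
        "coverage": coverage_series(times, bb_list, st_list, geometry),
        "bb_masks": np.array(bb_list),
        "streamer_masks": np.array(st_list),
    }
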