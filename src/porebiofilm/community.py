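"""Community-composition statistics for OTU abundance tables.

The architectural question has a community counterpart: do the base biofilm
and the streamers recruit different taxa?  The comparison operates on an
OTU table (rows = OTUs, columns = samples, integer read counts):
singleton removal and rarefaction to a common depth, presence-absence
(Jaccard) and abundance-weighted (Bray-Curtis) similarity with bootstrap
confidence intervals, shared/unique OTU accounting, and cross-sample
abundance correlation (optionally aggregated to a taxonomic level).

Tables are plain :class:`pandas.DataFrame` objects indexed by OTU id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimilarityResult",
    "remove_singletons",
    "rarefy",
    "jaccard",
    "bray_curtis",
    "bootstrap_ci",
    "shared_unique_counts",
    "abundance_correlation",
]


@dataclass(frozen=True)
class SimilarityResult:
    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.ci_high <= 1):
            raise ValueError("CI bounds must satisfy 0 <= low <= high <= 1")


def _as_counts(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative counts")
    return a


def remove_singletons(table: pd.DataFrame) -> pd.DataFrame:
    """Drop OTUs whose total count across all samples is exactly 1."""
    totals = table.sum(axis=1)
    return table.loc[totals != 1]


def rarefy(
    table: pd.DataFrame,
    depth: int = 5000,
    seed: int | None = None,
    drop_singletons: bool = True,
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Singleton OTUs (global count 1) are removed before rarefaction.  Samples
    with fewer than ``depth`` reads are dropped with a warning.  Subsampling
    uses the multivariate hypergeometric distribution, so every output
    sample sums to exactly ``depth`` and the procedure is deterministic for
    a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if drop_singletons:
        table = remove_singletons(table)
    rng = np.random.default_rng(seed)
    keep = {}
    for name in table.columns:
        counts = table[name].to_numpy()
        total = int(counts.sum())
        if total < depth:
            warnings.warn(
                f"sample {name!r} has {total} < {depth} reads; dropped", stacklevel=2
            )
            continue
        keep[name] = rng.multivariate_hypergeometric(counts.astype(np.int64), depth)
    out = pd.DataFrame(keep, index=table.index)
    return out


def jaccard(x, y) -> float:
    """Presence-absence Jaccard *similarity* |A∩B| / |A∪B|.

    Returns NaN when both samples are empty (undefined).
    """
    a = _as_counts(x) > 0
    b = _as_counts(y) > 0
    union = np.sum(a | b)
    if union == 0:
        return float("nan")
    return float(np.sum(a & b) / union)


def bray_curtis(x, y) -> float:
    """Bray-Curtis *similarity* on relative abundances.

    1 - sum|p_i - q_i| / sum(p_i + q_i) after normalising each sample to
    relative abundance; NaN if either sample is all-zero.
    """
    a = _as_counts(x)
    b = _as_counts(y)
    if a.sum() == 0 or b.sum() == 0:
        return float("nan")
    p = a / a.sum()
    q = b / b.sum()
    return float(1.0 - np.sum(np.abs(p - q)) / np.sum(p + q))


_METRICS = {"jaccard": jaccard, "bray_curtis": bray_curtis}


def _metric_rows(metric: str, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorised metric over paired rows of count matrices."""
    if metric == "jaccard":
        pa, pb = xa > 0, xb > 0
        union = (pa | pb).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(union > 0, (pa & pb).sum(axis=1) / union, np.nan)
    pa = xa / xa.sum(axis=1, keepdims=True)
    pb = xb / xb.sum(axis=1, keepdims=True)
    return 1.0 - 0.5 * np.abs(pa - pb).sum(axis=1)


def bootstrap_ci(
    table: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    metric: str = "jaccard",
    n: int = 1000,
    seed: int | None = None,
    variant: str = "reads",
    ci_method: str = "basic",
) -> SimilarityResult:
    """Bootstrap confidence interval for a pairwise similarity.

    ``variant='reads'`` (default): each randomisation redraws every sample's
    reads with replacement — a multinomial at the observed depth over the
    observed relative abundances — and recomputes the metric.  This is the
    variant whose CI is meaningful for an abundance-weighted metric.
    ``variant='otus'`` resamples OTU rows (incidence-matrix rows) with
    replacement instead; provided as a sensitivity check.

    ``ci_method='basic'`` (default) reflects the empirical 2.5/97.5
    percentiles around the point estimate (2*est - q97.5, 2*est - q2.5),
    which corrects the first-order downward bias that sampling zeros induce
    in plug-in similarities; ``'percentile'`` reports the raw percentiles.
    Bounds are clipped to [0, 1].
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if n < 2:
        raise ValueError("need at least 2 bootstrap draws")
    if ci_method not in ("basic", "percentile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    func = _METRICS[metric]
    a = table[sample_a].to_numpy(dtype=np.int64)
    b = table[sample_b].to_numpy(dtype=np.int64)
    point = func(a, b)
    rng = np.random.default_rng(seed)
    if variant == "reads":
        da, db = int(a.sum()), int(b.sum())
        ra = rng.multinomial(da, a / da, size=n)
        rb = rng.multinomial(db, b / db, size=n)
        vals = _metric_rows(metric, ra, rb)
    elif variant == "otus":
        m = a.size
        idx = rng.integers(0, m, size=(n, m))
        vals = _metric_rows(metric, a[idx], b[idx])
    else:
        raise ValueError(f"unknown bootstrap variant {variant!r}")
    q_lo, q_hi = np.nanpercentile(vals, [2.5, 97.5])
    if ci_method == "basic":
        lo, hi = 2 * point - q_hi, 2 * point - q_lo
    else:
        lo, hi = q_lo, q_hi
    return SimilarityResult(
        metric=metric,
        estimate=float(point),
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        n_boot=n,
    )


def shared_unique_counts(x, y) -> tuple[int, int, int, float]:
    """Presence-based OTU partition between two samples.

    Returns ``(shared, unique_x, unique_y, shared_read_fraction)`` where the
    last entry is the fraction of all reads (both samples pooled) carried by
    the shared OTUs.
    """
    a = _as_counts(x)
    b = _as_counts(y)
    pa, pb = a > 0, b > 0
    shared = pa & pb
    total = a.sum() + b.sum()
    frac = float((a[shared].sum() + b[shared].sum()) / total) if total > 0 else float("nan")
    return int(shared.sum()), int((pa & ~pb).sum()), int((pb & ~pa).sum()), frac


def abundance_correlation(
    table: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    taxonomy: pd.Series | None = None,
) -> tuple[float, int]:
    """Pearson r between relative abundances of two samples.

    With ``taxonomy`` (OTU id -> taxon string, e.g. family), counts are
    aggregated to that level first.  Only categories present in at least one
    sample enter the correlation.  Returns ``(r, n_categories)``.
    """
    sub = table[[sample_a, sample_b]]
    if taxonomy is not None:
        sub = sub.groupby(taxonomy.reindex(sub.index)).sum()
    a = sub[sample_a].to_numpy(dtype=float)
    b = sub[sample_b].to_numpy(dtype=float)
    nonzero = (a > 0) | (b > 0)
    a, b = a[nonzero], b[nonzero]
    if a.size < 3:
        raise ValueError("fewer than 3 nonzero categories")
    r, _ = stats.pearsonr(a / a.sum(), b / b.sum())
    return float(r), int(a.size)
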