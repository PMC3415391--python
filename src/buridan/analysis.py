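"""Cohort-level statistics: metric correlations, PCA, transition maps.

Works on the per-individual metrics table (one row per animal).  The
correlation analysis reports pairwise Pearson coefficients with a
two-sided significance mask; the PCA is a correlation-matrix PCA
(metrics standardized to unit variance first) so that metrics with
different units contribute equally.  The speed-threshold (ST) activity
metrics duplicate information carried by the median speed and are
discarded before the PCA.

Transition maps bin every 10 Hz sample of every individual of a group
onto a square grid over the platform bounding box, blur with a
ring-weighted kernel, and colour-scale to the 95% quantile of the
nonzero blurred counts so small density differences stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.decomposition import PCA

from .errors import ValidationError
from .metrics import MetricSet
from .preprocess import Trajectory

__all__ = ["CorrelationResult", "PCAResult", "TransitionGrid",
           "correlation_matrix", "pca_metrics", "transition_grid",
           "confidence_ellipse", "metrics_table"]

#: default blur weights by ring (self, 1st, 2nd, 3rd neighbours)
BLUR_WEIGHTS = (21.0, 16.0, 4.0, 1.0)


def metrics_table(metric_sets: list[MetricSet]) -> pd.DataFrame:
    """Stack MetricSet records into a DataFrame (id/group + numeric columns)."""
    import dataclasses
    return pd.DataFrame([dataclasses.asdict(m) for m in metric_sets],
                        columns=MetricSet.field_names())


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations over metrics across individuals."""

    metrics: list[str]
    r: pd.DataFrame              # symmetric, unit diagonal
    p: pd.DataFrame              # two-sided p-values (diagonal 0)
    significant: pd.DataFrame    # p < alpha mask
    alpha: float
    dropped: list[str]           # zero-variance metrics excluded


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the metrics table."""

    metrics: list[str]
    loadings: np.ndarray         # (n_components, n_metrics), rows orthonormal
    scores: pd.DataFrame         # per-individual scores, PC1..PCk columns
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class TransitionGrid:
    """Spatial density of cohort positions over the platform square."""

    raw: np.ndarray              # (n, n) counts, raw[iy, ix]
    blurred: np.ndarray
    ceiling: float               # colour-scale top: 95% quantile of nonzero blur
    extent: tuple[float, float, float, float]   # (xmin, xmax, ymin, ymax)


def _numeric_metrics(df: pd.DataFrame, exclude_st: bool = False) -> pd.DataFrame:
    cols = [c for c in df.columns if c not in ("id", "group")]
    if exclude_st:
        cols = [c for c in cols if c not in MetricSet.ST_FIELDS]
    return df[cols].astype(float)


def correlation_matrix(metric_sets: list[MetricSet] | pd.DataFrame,
                       alpha: float = 0.05) -> CorrelationResult:
    """Pairwise Pearson correlations with an (uncorrected) significance mask.

    Requires at least 3 individuals.  Metrics with zero variance (or any
    NaN) carry no correlation information and are excluded with a warning.
    """
    df = (metrics_table(metric_sets) if isinstance(metric_sets, list)
          else metric_sets)
    data = _numeric_metrics(df)
    if len(data) < 3:
        raise ValidationError("correlation analysis needs >= 3 individuals")
    dropped = [c for c in data.columns
               if data[c].isna().any() or float(data[c].std(ddof=1)) == 0.0]
    if dropped:
        warnings.warn(f"excluding degenerate metrics from correlation: {dropped}")
        data = data.drop(columns=dropped)
    cols = list(data.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(data.iloc[:, i], data.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationResult(metrics=cols, r=rdf, p=pdf,
                             significant=pdf < alpha, alpha=alpha,
                             dropped=dropped)


def pca_metrics(metric_sets: list[MetricSet] | pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of the metrics table.

    Metrics are standardized (zero mean, unit variance) before the
    decomposition, which makes the covariance PCA of the standardized
    table identical to an eigendecomposition of the Pearson correlation
    matrix; eigenvalues then sum to the number of retained metrics.  ST
    activity metrics and degenerate (constant or NaN) columns are
    removed first.
    """
    df = (metrics_table(metric_sets) if isinstance(metric_sets, list)
          else metric_sets)
    data = _numeric_metrics(df, exclude_st=True)
    if len(data) < 3:
        raise ValidationError("PCA needs >= 3 individuals")
    keep = [c for c in data.columns
            if not data[c].isna().any() and float(data[c].std(ddof=1)) > 0.0]
    if len(keep) < len(data.columns):
        warnings.warn(f"excluding degenerate metrics from PCA: "
                      f"{sorted(set(data.columns) - set(keep))}")
    data = data[keep]
    z = (data - data.mean()) / data.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    sdf = pd.DataFrame(scores, columns=names)
    if "id" in df.columns:
        sdf.insert(0, "id", df["id"].to_numpy())
    if "group" in df.columns:
        sdf.insert(1, "group", df["group"].to_numpy())
    return PCAResult(metrics=keep, loadings=pca.components_, scores=sdf,
                     variance_fraction=pca.explained_variance_ratio_,
                     eigenvalues=pca.explained_variance_)


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.8):
    """Confidence ellipse of a 2-D score cloud (e.g. a group in PC1/PC2).

    Returns (center, widths, angle_deg) where widths are the full axis
    lengths of the ``level`` confidence region under a bivariate normal
    fit (chi-square quantile on the score covariance).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need an (n>=3, 2) array of scores")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2)
    widths = 2.0 * np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    return center, widths[::-1], angle


def _ring_kernel(weights=BLUR_WEIGHTS) -> np.ndarray:
    """Blur kernel with ring weights by Chebyshev distance, normalized."""
    n = len(weights) - 1
    size = 2 * n + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    ring = np.maximum(np.abs(yy), np.abs(xx))
    k = np.asarray(weights, dtype=float)[ring]
    return k / k.sum()


def transition_grid(trajectories: list[Trajectory], grid_n: int = 60,
                    platform_radius_mm: float = 58.5,
                    blur_weights=BLUR_WEIGHTS) -> TransitionGrid:
    """Bin all samples of a group onto a grid, blur, set the colour ceiling.

    Every 10 Hz sample of every individual falls into one of
    ``grid_n x grid_n`` square bins covering the platform bounding box.
    The blur distributes each bin's mass over ring neighbourhoods with
    the given weights, renormalizing at the grid edge so total mass is
    conserved; the colour ceiling is the 95% quantile of the nonzero
    blurred counts and is computed *after* the blur.
    """
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    R = platform_radius_mm
    pos = np.concatenate([t.positions() for t in trajectories])
    edges = np.linspace(-R, R, grid_n + 1)
    raw, _, _ = np.histogram2d(pos[:, 1], pos[:, 0],
                               bins=[edges, edges])
    # clamp rim samples sitting exactly on +R into the last bin
    outside = int(pos.shape[0] - raw.sum())
    if outside:
        clipped = np.clip(pos, -R, R * (1 - 1e-12))
        raw, _, _ = np.histogram2d(clipped[:, 1], clipped[:, 0],
                                   bins=[edges, edges])
    kernel = _ring_kernel(blur_weights)
    # mass-conserving edge renormalization: each source bin spreads its
    # counts over the in-bounds part of the kernel only
    norm = ndimage.convolve(np.ones_like(raw), kernel, mode="constant")
    blurred = ndimage.convolve(raw / norm, kernel, mode="constant")
    nz = blurred[blurred > 0]
    ceiling = float(np.quantile(nz, 0.95)) if nz.size else 0.0
    return TransitionGrid(raw=raw, blurred=blurred, ceiling=ceiling,
                          extent=(-R, R, -R, R))
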