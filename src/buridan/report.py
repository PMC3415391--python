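"""PDF reports: per-individual pages and group-level summaries.

Group barplots show the mean and standard error of the per-individual
values (most metrics are already per-individual medians).  Transition
maps use the blurred density with the 95%-quantile colour ceiling, so a
few high-traffic bins saturate and the rest of the dynamic range stays
readable.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Circle

from .analysis import CorrelationResult, transition_grid
from .calibration import ArenaGeometry
from .preprocess import Trajectory, derive_steps

__all__ = ["per_individual_report", "group_report", "group_bar_stats"]


def group_bar_stats(metrics_df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Mean and standard error of one metric per group.

    The standard error is std(ddof=1)/sqrt(n) over the per-individual
    values of the group.
    """
    g = metrics_df.groupby("group")[column]
    return pd.DataFrame({"mean": g.mean(),
                         "sem": g.std(ddof=1) / np.sqrt(g.count()),
                         "n": g.count()})


def _draw_arena(ax, geometry: ArenaGeometry, show_stripes: bool) -> None:
    R = geometry.platform_radius_mm
    ax.add_patch(Circle((0, 0), R, fill=False, color="0.4"))
    if show_stripes:
        for sx, sy in geometry.stripe_centers_mm:
            ax.plot([sx], [sy], marker="s", ms=8, color="black")
    lim = max(R, geometry.stripe_distance_mm if show_stripes else R) * 1.1
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")


def per_individual_report(trajectories: dict[str, Trajectory], path,
                          geometry: ArenaGeometry | None = None,
                          show_stripes: bool | None = None) -> None:
    """One PDF page per individual: arena trajectory + speed over time.

    Stripe markers are drawn only when the experiment had stripes
    (``show_stripes`` defaults to whether the geometry defines a stripe
    width).
    """
    geometry = geometry or ArenaGeometry()
    if show_stripes is None:
        show_stripes = geometry.stripe_width_mm is not None
    with PdfPages(path) as pdf:
        for id_, traj in trajectories.items():
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
            for b in traj.bursts:
                ax1.plot(b.x, b.y, lw=0.5, color="tab:blue")
            _draw_arena(ax1, geometry, show_stripes)
            ax1.set_title(id_)
            steps = derive_steps(traj)
            ax2.plot(steps.t, steps.speed, lw=0.4, color="tab:red")
            ax2.set_xlabel("time (s)")
            ax2.set_ylabel("speed (mm/s)")
            ax2.set_title("speed over time")
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)


def _plot_correlation(ax, corr: CorrelationResult) -> None:
    """Dot-matrix correlation plot: only significant cells are drawn."""
    k = len(corr.metrics)
    for i in range(k):
        for j in range(k):
            if i == j or not corr.significant.iloc[i, j]:
                continue
            r = corr.r.iloc[i, j]
            ax.scatter(j, k - 1 - i, s=200 * abs(r),
                       color="tab:green" if r > 0 else "tab:purple")
    ax.set_xticks(range(k), corr.metrics, rotation=90, fontsize=6)
    ax.set_yticks(range(k), corr.metrics[::-1], fontsize=6)
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    ax.set_title(f"significant correlations (alpha={corr.alpha})")


def group_report(metrics_df: pd.DataFrame,
                 trajectories_by_group: dict[str, list[Trajectory]], path,
                 geometry: ArenaGeometry | None = None,
                 correlations: dict[str, CorrelationResult] | None = None,
                 grid_n: int = 60) -> None:
    """Group-level PDF: metric barplots, transition maps, correlations."""
    geometry = geometry or ArenaGeometry()
    metric_cols = [c for c in metrics_df.columns if c not in ("id", "group")]
    with PdfPages(path) as pdf:
        ncols = 3
        nrows = math.ceil(len(metric_cols) / ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(11, 3 * nrows))
        for ax, col in zip(np.ravel(axes), metric_cols):
            st = group_bar_stats(metrics_df, col)
            ax.bar(st.index, st["mean"], yerr=st["sem"], capsize=3,
                   color="0.8", edgecolor="black")
            ax.set_title(col, fontsize=8)
            ax.tick_params(axis="x", rotation=45, labelsize=7)
        for ax in np.ravel(axes)[len(metric_cols):]:
            ax.axis("off")
        fig.suptitle("group means +/- s.e. of per-individual values")
        fig.tight_layout()
        pdf.savefig(fig)
        plt.close(fig)

        for group, trajs in trajectories_by_group.items():
            grid = transition_grid(trajs, grid_n, geometry.platform_radius_mm)
            fig, ax = plt.subplots(figsize=(5.5, 5))
            shown = np.where(grid.blurred > 0, grid.blurred, np.nan)
            im = ax.imshow(shown, origin="lower", extent=grid.extent,
                           vmin=0, vmax=grid.ceiling or None, cmap="jet")
            ax.add_patch(Circle((0, 0), geometry.platform_radius_mm,
                                fill=False, color="black"))
            ax.set_title(f"transition map: {group}")
            fig.colorbar(im, ax=ax, label="blurred counts (ceiling = 95% quantile)")
            pdf.savefig(fig)
            plt.close(fig)

        for group, corr in (correlations or {}).items():
            fig, ax = plt.subplots(figsize=(6.5, 6.5))
            _plot_correlation(ax, corr)
            ax.set_title(f"{group}: " + ax.get_title())
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
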