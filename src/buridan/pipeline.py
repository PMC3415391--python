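"""End-to-end analysis pipeline: from files on disk to the five outputs.

``analyze_experiments`` is the one-call analysis workflow: a group
file names the experiments, each experiment contributes a metadata XML
and a raw pixel track, and the pipeline calibrates, preprocesses,
computes the per-individual metrics and writes (1) an imported-session
archive, (2) an analyzed-session archive, (3) the metrics CSV, (4) a
group report PDF (barplots, transition maps, correlation plots) and
(5) a per-individual report PDF.

``write_cohort`` serializes simulated walks in the identical track/XML
dialect, so simulated cohorts flow through the same analysis path as
real recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io as bio
from .analysis import correlation_matrix, metrics_table
from .calibration import ArenaGeometry, PixelCircle, mm_to_px, to_arena_mm
from .errors import ValidationError
from .metrics import ActivityConfig, compute_metrics
from .preprocess import FilterConfig, derive_steps, preprocess
from .simulate import SimWalk

__all__ = ["analyze_experiments", "write_cohort", "NOMINAL_CIRCLE"]

#: nominal camera calibration used when serializing simulated cohorts
#: (~0.35 mm per pixel on a 640x480 sensor)
NOMINAL_CIRCLE = PixelCircle(cx_px=320.0, cy_px=240.0, r_px=167.0)


def analyze_experiments(data_dir: str | Path, groups_file: str | Path,
                        out_dir: str | Path,
                        filter_config: FilterConfig | None = None,
                        activity_config: ActivityConfig | None = None,
                        geometry: ArenaGeometry | None = None,
                        alpha: float = 0.05,
                        write_reports: bool = True) -> dict:
    """Run the full analysis for every experiment named in the group file.

    Returns a dict with the metrics table, trajectories, groups and the
    per-group correlation results; writes the five standard outputs into
    ``out_dir``.
    """
    from .report import group_report, per_individual_report

    filter_config = filter_config or FilterConfig()
    activity_config = activity_config or ActivityConfig()
    geometry = geometry or ArenaGeometry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assignment = bio.read_groups(groups_file, data_dir)
    trajectories: dict = {}
    groups: dict[str, str] = {}
    metric_sets = []
    for xml_path, label in assignment:
        meta = bio.read_meta(xml_path)
        track = bio.read_track(meta.data_file)
        traj = to_arena_mm(track, meta.platform_circle,
                           geometry.platform_radius_mm)
        traj = preprocess(traj, filter_config)
        steps = derive_steps(traj, filter_config)
        id_ = meta.fly_label
        if id_ in trajectories:
            raise ValidationError(f"duplicate fly label {id_!r}")
        trajectories[id_] = traj
        groups[id_] = label
        metric_sets.append(compute_metrics(traj, steps, geometry,
                                           activity_config, id=id_, group=label))

    bio.save_session(out_dir / "imported_session.zip", trajectories, groups)
    bio.write_metrics_csv(metric_sets, out_dir / "metrics.csv")
    df = metrics_table(metric_sets)

    correlations = {}
    for label in sorted(set(groups.values())):
        sub = df[df["group"] == label]
        if len(sub) >= 3:
            correlations[label] = correlation_matrix(sub, alpha)

    bio.save_session(out_dir / "analyzed_session.zip", trajectories, groups,
                     metrics=metric_sets)
    if write_reports:
        by_group = {}
        for id_, label in groups.items():
            by_group.setdefault(label, []).append(trajectories[id_])
        group_report(df, by_group, out_dir / "group_report.pdf", geometry,
                     correlations)
        per_individual_report(trajectories, out_dir / "individuals.pdf",
                              geometry)
    return {"metrics": df, "metric_sets": metric_sets,
            "trajectories": trajectories, "groups": groups,
            "correlations": correlations}


def write_cohort(walks: list[SimWalk], out_dir: str | Path,
                 group_label: str | None = None,
                 circle: PixelCircle = NOMINAL_CIRCLE) -> Path:
    """Write simulated walks as track + XML files plus a group file.

    Positions are mapped from mm to pixels with the nominal calibration
    so the files are indistinguishable in format from real recordings.
    Returns the path of the written group file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, walk in enumerate(walks, start=1):
        label = group_label or walk.params.kind
        name = f"{label}_{i:02d}"
        x_px, y_px = mm_to_px(walk.positions[:, 0], walk.positions[:, 1],
                              circle, walk.params.platform_radius_mm)
        n = walk.positions.shape[0]
        t_ms = (np.arange(n) * (1000.0 / walk.params.sample_hz)).astype(np.int64)
        track = bio.RawTrack(t_ms=t_ms, x_px=x_px, y_px=y_px,
                             burst=np.zeros(n, dtype=np.int64))
        bio.write_track(track, out_dir / f"{name}.dat")
        meta = bio.ExperimentMeta(
            fly_label=name, data_file=out_dir / f"{name}.dat",
            duration_s=n / walk.params.sample_hz,
            platform_circle=circle, resolution=(640, 480))
        bio.write_meta(meta, out_dir / f"{name}.xml")
        lines.append(f"{name}.xml\t{label}")
    groups_path = out_dir / "groups.txt"
    groups_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return groups_path
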