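"""File dialects of the tracking/analysis chain.

Three input formats and two outputs:

* **Track file** — plain tab-separated text, four columns per line: time
  in ms, X and Y in pixels, and the burst number.  The burst number is
  incremented whenever the animal was lost or left the platform, so a
  track is a sequence of independent segments.
* **Metadata file** — one small flat XML document per experiment holding
  the fly label, data file name, experiment duration, stripe width and
  positions (absent for stripe-free experiments), the calibrated platform
  circle, camera resolution and start timestamp.  Unknown extra tags are
  ignored for forward compatibility.
* **Group file** — two whitespace-separated columns mapping XML file
  names (optionally with subfolder prefixes) to group labels.
* **Metrics CSV** — one row per individual, one column per metric
  (RFC 4180, readable by any spreadsheet).
* **Session archive** — a zip of CSV/JSON tables capturing imported or
  analyzed state so a session can be reloaded without re-import.

Example metadata document::

    <experiment>
      <fly_label>fly_1</fly_label>
      <data_file>fly_1.dat</data_file>
      <duration_s>900</duration_s>
      <stripe_width_mm>30</stripe_width_mm>
      <stripe_positions>90 -90</stripe_positions>
      <platform cx="320" cy="240" r="167"/>
      <resolution width="640" height="480"/>
      <started_at>2024-05-01T10:00:00</started_at>
    </experiment>
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .calibration import PixelCircle
from .errors import ParseError, ValidationError
from .metrics import MetricSet
from .preprocess import Burst, Trajectory

__all__ = [
    "RawTrack", "ExperimentMeta", "GroupAssignment",
    "read_track", "write_track", "read_meta", "write_meta",
    "read_groups", "write_metrics_csv", "read_metrics_csv",
    "save_session", "load_session",
]


@dataclass
class RawTrack:
    """A raw tracker output: timestamped pixel positions with burst numbers."""

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    burst: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.burst = np.asarray(self.burst, dtype=np.int64)
        n = self.t_ms.size
        if not (self.x_px.size == self.y_px.size == self.burst.size == n):
            raise ValidationError("track columns must have equal length")
        if n and np.any(np.diff(self.burst) < 0):
            raise ValidationError("burst numbers must be non-decreasing")
        for b in np.unique(self.burst):
            t = self.t_ms[self.burst == b]
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"timestamps not strictly increasing within burst {b}")

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def n_bursts(self) -> int:
        return int(np.unique(self.burst).size)


@dataclass
class ExperimentMeta:
    """Per-experiment metadata as written by the tracker."""

    fly_label: str
    data_file: Path
    duration_s: float
    platform_circle: PixelCircle
    resolution: tuple[int, int]
    started_at: str = ""
    stripe_width_mm: float | None = None
    stripe_positions_deg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")


@dataclass
class GroupAssignment:
    """Resolved mapping from metadata files to group labels."""

    entries: list[tuple[Path, str]]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_track(path: str | Path) -> RawTrack:
    """Parse a four-column tab-separated track file.

    Lines must carry at least four tab-separated fields (time ms, x px,
    y px, burst); blank lines are skipped.  Raises :class:`ParseError`
    naming the first malformed line, and :class:`ValidationError` if time
    is not strictly increasing within a burst.
    """
    path = Path(path)
    t, x, y, b = [], [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}")
            try:
                t.append(int(float(parts[0])))
                x.append(float(parts[1]))
                y.append(float(parts[2]))
                b.append(int(parts[3]))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    return RawTrack(t_ms=np.array(t, dtype=np.int64), x_px=np.array(x),
                    y_px=np.array(y), burst=np.array(b, dtype=np.int64))


def write_track(track: RawTrack, path: str | Path) -> None:
    """Write a track in the tab-separated tracker dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for t, x, y, b in zip(track.t_ms, track.x_px, track.y_px, track.burst):
            fh.write(f"{t}\t{x:.6g}\t{y:.6g}\t{b}\n")


def _text(root, tag: str) -> str | None:
    el = root.find(tag)
    return None if el is None or el.text is None else el.text.strip()


def read_meta(path: str | Path) -> ExperimentMeta:
    """Parse an experiment metadata XML file.

    Stripe fields may be absent (endogenous-locomotion experiments);
    platform circle and duration are mandatory.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path.name}: not well-formed XML: {exc}") from None
    duration = _text(root, "duration_s")
    platform = root.find("platform")
    if duration is None:
        raise ValidationError(f"{path.name}: missing <duration_s>")
    if platform is None:
        raise ValidationError(f"{path.name}: missing <platform> element")
    try:
        circle = PixelCircle(float(platform.get("cx")), float(platform.get("cy")),
                             float(platform.get("r")))
    except (TypeError, ValueError):
        raise ValidationError(
            f"{path.name}: <platform> needs numeric cx, cy, r attributes") from None
    res_el = root.find("resolution")
    resolution = (640, 480)
    if res_el is not None:
        resolution = (int(res_el.get("width")), int(res_el.get("height")))
    width = _text(root, "stripe_width_mm")
    positions = _text(root, "stripe_positions")
    return ExperimentMeta(
        fly_label=_text(root, "fly_label") or path.stem,
        data_file=path.parent / (_text(root, "data_file") or f"{path.stem}.dat"),
        duration_s=float(duration),
        platform_circle=circle,
        resolution=resolution,
        started_at=_text(root, "started_at") or "",
        stripe_width_mm=None if width is None else float(width),
        stripe_positions_deg=(None if positions is None
                              else tuple(float(v) for v in positions.split())[:2]),
    )


def write_meta(meta: ExperimentMeta, path: str | Path) -> None:
    """Serialize experiment metadata to the flat XML dialect."""
    root = etree.Element("experiment")
    etree.SubElement(root, "fly_label").text = meta.fly_label
    etree.SubElement(root, "data_file").text = Path(meta.data_file).name
    etree.SubElement(root, "duration_s").text = f"{meta.duration_s:g}"
    if meta.stripe_width_mm is not None:
        etree.SubElement(root, "stripe_width_mm").text = f"{meta.stripe_width_mm:g}"
    if meta.stripe_positions_deg is not None:
        etree.SubElement(root, "stripe_positions").text = " ".join(
            f"{v:g}" for v in meta.stripe_positions_deg)
    c = meta.platform_circle
    etree.SubElement(root, "platform", cx=f"{c.cx_px:g}", cy=f"{c.cy_px:g}",
                     r=f"{c.r_px:g}")
    etree.SubElement(root, "resolution", width=str(meta.resolution[0]),
                     height=str(meta.resolution[1]))
    if meta.started_at:
        etree.SubElement(root, "started_at").text = meta.started_at
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_groups(path: str | Path, data_root: str | Path = ".") -> GroupAssignment:
    """Parse a group file and resolve its XML paths against ``data_root``.

    Each non-blank line holds an XML file name (subfolder prefixes such
    as ``experiment_1/fly_1.xml`` are honoured) and a group label,
    separated by any run of tabs or spaces.  Resolution is total: a
    duplicate XML name or an unresolvable path fails the whole read.
    """
    path = Path(path)
    data_root = Path(data_root)
    entries: list[tuple[Path, str]] = []
    seen: set[str] = set()
    missing: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 'xml_file group_label', "
                    f"got {len(parts)} fields")
            xml_name, label = parts
            if xml_name in seen:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate entry for {xml_name!r}")
            seen.add(xml_name)
            resolved = data_root / xml_name
            if not resolved.is_file():
                missing.append(str(resolved))
            entries.append((resolved, label))
    if missing:
        raise ValidationError("missing metadata files: " + ", ".join(missing))
    return GroupAssignment(entries=entries)


def write_metrics_csv(metric_sets: list[MetricSet], path: str | Path) -> None:
    """Write per-individual metrics as an RFC 4180 CSV, one row per animal.

    All records must share the same field set (they do for
    :class:`~buridan.metrics.MetricSet`); floats are written with 12
    significant digits so a read-back round-trips to at least 10.
    """
    names = MetricSet.field_names()
    for ms in metric_sets:
        got = [f.name for f in dataclasses.fields(ms)]
        if got != names:
            raise ValidationError("heterogeneous metric records")
    df = pd.DataFrame([dataclasses.asdict(ms) for ms in metric_sets],
                      columns=names)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back into a DataFrame (id/group as strings)."""
    return pd.read_csv(path, dtype={"id": str, "group": str})


def _traj_frame(traj: Trajectory) -> pd.DataFrame:
    rows = [pd.DataFrame({"burst": bi, "t": b.t, "x": b.x, "y": b.y})
            for bi, b in enumerate(traj.bursts)]
    return (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["burst", "t", "x", "y"]))


def save_session(path: str | Path, trajectories: dict[str, Trajectory],
                 groups: dict[str, str],
                 metrics: list[MetricSet] | None = None) -> None:
    """Archive a session (trajectories + grouping, optionally metrics).

    The archive is a zip of per-individual trajectory CSVs plus a JSON
    manifest, so an analysis can be redone with different thresholds
    without re-importing raw data.
    """
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        manifest = {"ids": list(trajectories), "groups": groups,
                    "has_metrics": metrics is not None}
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for id_, traj in trajectories.items():
            buf = _io.StringIO()
            _traj_frame(traj).to_csv(buf, index=False, float_format="%.12g")
            zf.writestr(f"trajectories/{id_}.csv", buf.getvalue())
        if metrics is not None:
            buf = _io.StringIO()
            pd.DataFrame([dataclasses.asdict(m) for m in metrics]).to_csv(
                buf, index=False, float_format="%.12g")
            zf.writestr("metrics.csv", buf.getvalue())


def load_session(path: str | Path):
    """Load a session archive; returns (trajectories, groups, metrics_df)."""
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        trajectories: dict[str, Trajectory] = {}
        for id_ in manifest["ids"]:
            df = pd.read_csv(zf.open(f"trajectories/{id_}.csv"))
            bursts = [Burst(t=g["t"].to_numpy(), x=g["x"].to_numpy(),
                            y=g["y"].to_numpy())
                      for _, g in df.groupby("burst", sort=True)]
            trajectories[id_] = Trajectory(bursts=bursts)
        metrics_df = (pd.read_csv(zf.open("metrics.csv"))
                      if manifest.get("has_metrics") else None)
    return trajectories, manifest["groups"], metrics_df
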