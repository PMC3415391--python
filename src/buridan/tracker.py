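"""Offline centroid tracker for circular-arena frames.

Runs the classic dark-spot detection chain on stored grayscale frames
(no live camera needed): the animal appears as a dark spot on a bright
background; each frame is thresholded to black-and-white, inverted,
Gaussian-blurred, and the bright dots above a second threshold become
candidate positions (the brightest pixel of each connected dot).  Among
multiple candidates the one nearest the previous position wins; on the
first frame (or after the animal was lost) the globally brightest wins.
A detection outside the calibrated platform circle, or no detection at
all, increments the burst number — each maximal undetectable run starts
a new burst.

A synthetic-frame renderer inverts the calibration mapping so the whole
chain is testable without a camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian
from skimage.measure import label, regionprops

from .calibration import PixelCircle, mm_to_px
from .errors import ValidationError

__all__ = ["DetectorConfig", "TrackState", "detect", "advance",
           "track_frames", "synth_frames"]


@dataclass(frozen=True)
class DetectorConfig:
    """User-tunable detection parameters.

    binarize_threshold : intensities below this are foreground (the
        animal is darker than the background).
    blur_sigma : Gaussian blur width in pixels applied to the inverted
        binary image.
    dot_threshold : blurred intensity a pixel must exceed to belong to a
        candidate dot (on the blurred 0..1 scale).
    platform : calibrated rim circle; detections outside it are treated
        as the animal having left the platform.
    """

    platform: PixelCircle
    binarize_threshold: float = 128.0
    blur_sigma: float = 2.0
    dot_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.binarize_threshold <= 255):
            raise ValidationError("binarize_threshold outside intensity range")
        if self.blur_sigma <= 0:
            raise ValidationError("blur_sigma must be > 0")


@dataclass
class TrackState:
    """Mutable tracking state across frames."""

    last_position: tuple[float, float] | None = None
    burst: int = 0
    missing: bool = False         # inside an undetectable run?
    rows: list[tuple[int, float, float, int]] = field(default_factory=list)


def detect(frame: np.ndarray, config: DetectorConfig,
           state: TrackState | None = None) -> tuple[float, float] | None:
    """Detect the animal in one frame; returns (x_px, y_px) or None.

    Candidates are the brightest pixels of each connected bright dot in
    the blurred, inverted, thresholded image (8-connectivity; intensity
    ties broken toward the lowest row, then column).  The candidate
    nearest the previous position is chosen, or the globally brightest
    if there is no previous position.  Returns None when no dot exists
    or the chosen candidate lies outside the platform circle.
    """
    img = np.asarray(frame, dtype=float)
    binary = (img < config.binarize_threshold).astype(float)   # invert: spot -> 1
    blurred = gaussian(binary, sigma=config.blur_sigma)
    mask = blurred > config.dot_threshold
    if not mask.any():
        return None
    labels = label(mask, connectivity=2)
    candidates: list[tuple[float, float, float]] = []   # (peak, x, y)
    for region in regionprops(labels):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        vals = blurred[rr, cc]
        # coords are in scan order, so argmax picks lowest (row, col) on ties
        best = int(np.argmax(vals))
        candidates.append((float(vals[best]), float(cc[best]), float(rr[best])))
    last = state.last_position if state is not None else None
    if last is None:
        _, x, y = max(candidates, key=lambda c: c[0])
    else:
        _, x, y = min(candidates,
                      key=lambda c: math.hypot(c[1] - last[0], c[2] - last[1]))
    c = config.platform
    if math.hypot(x - c.cx_px, y - c.cy_px) > c.r_px:
        return None
    return (x, y)


def advance(state: TrackState, detection: tuple[float, float] | None,
            t_ms: int) -> TrackState:
    """Fold one detection into the track state.

    A present detection emits a (t, x, y, burst) row and updates the
    last position; an absent one starts (at most once per undetectable
    run) a new burst and clears the last position, so the nearest-to-
    previous rule resets when the animal reappears.
    """
    if detection is None:
        if not state.missing:
            state.burst += 1
            state.missing = True
            state.last_position = None
        return state
    x, y = detection
    state.rows.append((int(t_ms), x, y, state.burst))
    state.last_position = (x, y)
    state.missing = False
    return state


def track_frames(frames, config: DetectorConfig, t_ms=None):
    """Run the full chain over a frame sequence; returns a RawTrack.

    ``t_ms`` supplies per-frame timestamps (default: 100 ms spacing,
    i.e. 10 Hz capture).
    """
    from .io import RawTrack

    frames = list(frames)
    if t_ms is None:
        t_ms = [100 * i for i in range(len(frames))]
    state = TrackState()
    for frame, t in zip(frames, t_ms):
        advance(state, detect(frame, config, state), t)
    rows = state.rows
    if not rows:
        return RawTrack(t_ms=np.empty(0, dtype=np.int64), x_px=np.empty(0),
                        y_px=np.empty(0), burst=np.empty(0, dtype=np.int64))
    arr = np.array(rows, dtype=float)
    return RawTrack(t_ms=arr[:, 0].astype(np.int64), x_px=arr[:, 1],
                    y_px=arr[:, 2], burst=arr[:, 3].astype(np.int64))


def synth_frames(positions_mm: np.ndarray, circle: PixelCircle,
                 shape: tuple[int, int] = (240, 240),
                 noise_sigma: float = 0.0,
                 seed: int | None = 0,
                 platform_radius_mm: float = 58.5,
                 spot_sigma_px: float = 2.0,
                 spot_depth: float = 200.0):
    """Render synthetic frames for a trajectory (the calibration inverse).

    Each mm position maps to pixels and is drawn as a dark Gaussian spot
    of the given depth on a uniform bright (255) background; optional
    additive Gaussian noise of ``noise_sigma`` intensity units is applied
    per frame.  Yields uint8 frames of the given (height, width).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    positions_mm = np.asarray(positions_mm, dtype=float)
    xs, ys = mm_to_px(positions_mm[:, 0], positions_mm[:, 1], circle,
                      platform_radius_mm)
    half = int(math.ceil(4 * spot_sigma_px))
    for x, y in zip(xs, ys):
        frame = np.full((h, w), 255.0)
        cx, cy = int(round(x)), int(round(y))
        r0, r1 = max(0, cy - half), min(h, cy + half + 1)
        c0, c1 = max(0, cx - half), min(w, cx + half + 1)
        if r0 < r1 and c0 < c1:
            yy, xx = np.mgrid[r0:r1, c0:c1]
            frame[r0:r1, c0:c1] -= spot_depth * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * spot_sigma_px ** 2))
        if noise_sigma > 0:
            frame += rng.normal(0.0, noise_sigma, size=frame.shape)
        yield np.clip(frame, 0, 255).astype(np.uint8)
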