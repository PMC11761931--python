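"""Top-view walking features from per-frame bird detections.

A bird's detection sequence (bounding box + head keypoint at a fixed frame
rate) is turned into four features of its walk through the corridor:

* **lateral body oscillation** — mean absolute residual (px) of the
  bounding-box centre around a degree-5 polynomial movement trajectory
  fitted to the lateral coordinate,
* **step count** — number of times the centre point crosses that fitted
  trajectory (residual sign changes), reflecting the lateral shift of the
  centre of gravity onto the supporting leg at each step,
* **completion time** — traversal duration in seconds at the recording
  frame rate,
* **length-width ratio** — framewise bounding-box extent along the walk
  axis over extent across the corridor.

Processing order is fixed: build track -> mask backward-facing frames ->
interpolate short gaps -> moving-average smoothing -> polynomial fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

OBSERVED, MASKED, IMPUTED = 0, 1, 2
STATUS_NAMES = {OBSERVED: "observed", MASKED: "masked", IMPUTED: "imputed"}

DEFAULT_FPS = 11.0
DEFAULT_MAX_GAP = 5
DEFAULT_WINDOW = 3
MIN_FIT_FRAMES = 12   # twice the quintic's parameter count; shorter tracks flagged
MIN_FRAMES_HARD = 7   # below this a quintic interpolates exactly -> reject


@dataclass
class Track:
    """Ordered, gap-annotated per-frame series for one bird.

    Coordinate arrays are float and NaN on masked frames; ``frames`` is
    strictly increasing and contiguous after :func:`build_track`.
    """

    bird_id: str
    fps: float
    frames: np.ndarray
    cx: np.ndarray
    cy: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    length: np.ndarray  # box x-extent (along the walk axis)
    width: np.ndarray   # box y-extent (across the corridor)
    status: np.ndarray
    excluded: bool = False
    masked_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrajectoryFit:
    """Degree-5 polynomial movement trajectory with its residual series."""

    bird_id: str
    degree: int
    coefficients: np.ndarray       # power-basis coefficients, low order first
    abscissa: np.ndarray           # frame index (or longitudinal position)
    fitted: np.ndarray
    residuals: np.ndarray
    short_track: bool = False


@dataclass
class WalkFeatures:
    bird_id: str
    lateral_oscillation: float
    step_count: int
    completion_time: float
    lw_ratio_series: np.ndarray
    n_frames: int
    masked_fraction: float
    excluded: bool


# ---------------------------------------------------------------------------
# Track construction and preprocessing
# ---------------------------------------------------------------------------

def build_track(records: pd.DataFrame, fps: float = DEFAULT_FPS) -> Track:
    """Assemble a contiguous track from one bird's detection records.

    The centre is the bounding-box midpoint. Frames absent from the input
    are inserted with status ``masked`` so that downstream gap handling
    sees one uniform representation.
    """
    if len(records) == 0:
        raise ValueError("empty detection sequence")
    frames = records["frame"].to_numpy(int)
    if not np.all(np.diff(frames) > 0):
        raise ValueError("detection records must be sorted by frame with unique frames")
    bird_id = str(records["bird_id"].iloc[0])
    full = np.arange(frames[0], frames[-1] + 1)
    n = len(full)

    def grid(values: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        out[frames - frames[0]] = values
        return out

    x0, y0 = records["x_min"].to_numpy(float), records["y_min"].to_numpy(float)
    x1, y1 = records["x_max"].to_numpy(float), records["y_max"].to_numpy(float)
    if np.any(x1 <= x0) or np.any(y1 <= y0):
        raise ValueError("degenerate bounding box in detection records")
    status = np.full(n, MASKED, dtype=int)
    status[frames - frames[0]] = OBSERVED
    return Track(
        bird_id=bird_id, fps=float(fps), frames=full,
        cx=grid((x0 + x1) / 2), cy=grid((y0 + y1) / 2),
        head_x=grid(records["head_x"].to_numpy(float)),
        head_y=grid(records["head_y"].to_numpy(float)),
        length=grid(x1 - x0), width=grid(y1 - y0),
        status=status,
    )


def mask_backward_facing(track: Track, walk_direction: int = 1) -> Track:
    """Mask frames on which the bird is not facing the end of the walkway.

    A frame is kept iff the head keypoint lies at or beyond the box centre
    along ``walk_direction`` (+1 for walks toward +x, -1 toward -x); the
    exact tie counts as forward so masking stays conservative.
    """
    if walk_direction not in (+1, -1):
        raise ValueError("walk_direction must be +1 or -1")
    backward = (track.head_x - track.cx) * walk_direction < 0
    backward &= track.status == OBSERVED
    status = track.status.copy()
    status[backward] = MASKED
    new = replace(
        track, status=status,
        cx=track.cx.copy(), cy=track.cy.copy(),
        head_x=track.head_x.copy(), head_y=track.head_y.copy(),
        length=track.length.copy(), width=track.width.copy(),
    )
    for arr in (new.cx, new.cy, new.head_x, new.head_y, new.length, new.width):
        arr[backward] = np.nan
    new.masked_fraction = float(np.mean(new.status == MASKED))
    return new


def _masked_runs(status: np.ndarray):
    """(start, stop) half-open index ranges of consecutive masked frames."""
    runs = []
    i, n = 0, len(status)
    while i < n:
        if status[i] == MASKED:
            j = i
            while j < n and status[j] == MASKED:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(track: Track, max_gap: int = DEFAULT_MAX_GAP) -> Track:
    """Linearly impute masked runs of length <= ``max_gap`` frames.

    Masked leading/trailing frames are trimmed (no extrapolation). A track
    with any internal masked run longer than ``max_gap`` is flagged
    ``excluded``: such birds leave the feature analysis rather than being
    imputed aggressively. An empty remainder raises.
    """
    status = track.status.copy()
    keep = np.ones(len(status), dtype=bool)
    runs = _masked_runs(status)
    for start, stop in runs:
        if start == 0 or stop == len(status):
            keep[start:stop] = False
    if not keep.any():
        raise ValueError(f"track {track.bird_id}: no observed frames remain after trimming")
    sl = slice(np.argmax(keep), len(keep) - np.argmax(keep[::-1]))
    arrays = {
        name: getattr(track, name)[sl].copy()
        for name in ("frames", "cx", "cy", "head_x", "head_y", "length", "width", "status")
    }
    status = arrays.pop("status")
    frames = arrays.pop("frames")
    excluded = track.excluded
    for start, stop in _masked_runs(status):
        gap = stop - start
        if gap > max_gap:
            excluded = True
            continue
        for arr in arrays.values():
            lo, hi = arr[start - 1], arr[stop]
            w = np.arange(1, gap + 1) / (gap + 1)
            arr[start:stop] = lo + w * (hi - lo)
        status[start:stop] = IMPUTED
    return replace(
        track, frames=frames, status=status, excluded=excluded,
        masked_fraction=float(np.mean(status == MASKED)), **arrays,
    )


def smooth(track: Track, window: int = DEFAULT_WINDOW) -> Track:
    """Centred moving average of the centre coordinates.

    The window truncates at the series ends (no padding, no invented
    data). Requires an odd window >= 1 and no unresolved masked frames.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if np.any(track.status == MASKED):
        raise ValueError("smooth() requires gaps to be interpolated or trimmed first")
    half = window // 2

    def ma(values: np.ndarray) -> np.ndarray:
        out = np.empty_like(values)
        n = len(values)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[i] = values[lo:hi].mean()
        return out

    return replace(track, cx=ma(track.cx), cy=ma(track.cy))


# ---------------------------------------------------------------------------
# Trajectory fit and features
# ---------------------------------------------------------------------------

def fit_trajectory(track: Track, against: str = "time") -> TrajectoryFit:
    """Least-squares degree-5 polynomial movement trajectory.

    The lateral (y) centre coordinate is regressed on the frame index
    (``against='time'``) or on the longitudinal coordinate
    (``against='position'``). Fewer than 7 frames would make the quintic an
    exact interpolant and is rejected; fewer than ``MIN_FIT_FRAMES`` flags
    the fit as short.
    """
    if np.any(track.status == MASKED):
        raise ValueError("fit_trajectory() requires a fully resolved track")
    n = len(track)
    if n < MIN_FRAMES_HARD:
        raise ValueError(f"track {track.bird_id}: {n} frames cannot support a quintic fit")
    if against == "time":
        t = track.frames.astype(float)
    elif against == "position":
        t = track.cx.astype(float)
    else:
        raise ValueError("against must be 'time' or 'position'")
    y = track.cy.astype(float)
    # Fit in a scaled domain for conditioning; convert back to power basis.
    series = np.polynomial.Polynomial.fit(t, y, 5)
    fitted = series(t)
    return TrajectoryFit(
        bird_id=track.bird_id, degree=5,
        coefficients=series.convert().coef,
        abscissa=t, fitted=fitted, residuals=y - fitted,
        short_track=n < MIN_FIT_FRAMES,
    )


def lateral_oscillation(fit: TrajectoryFit) -> float:
    """Mean absolute residual around the movement trajectory, in px."""
    return float(np.mean(np.abs(fit.residuals)))


def _sign_series(residuals: np.ndarray) -> np.ndarray:
    """Signs with zeros inheriting the previous nonzero sign (leading zeros
    take the first nonzero sign), so a tangential touch of the trajectory is
    not double-counted as two crossings."""
    s = np.sign(residuals)
    nz = np.flatnonzero(s)
    if len(nz) == 0:
        return s
    s[: nz[0]] = s[nz[0]]
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return s


def step_count(fit: TrajectoryFit) -> int:
    """Number of residual sign changes: crossings of the centre point over
    the fitted movement trajectory."""
    s = _sign_series(fit.residuals.copy())
    return int(np.sum(s[1:] != s[:-1]))


def completion_time(track: Track) -> float:
    """Walk duration in seconds: frame count (first to last detection,
    inclusive) divided by the frame rate."""
    if len(track) == 0:
        raise ValueError("empty track")
    if track.fps <= 0:
        raise ValueError("fps must be positive")
    return len(track) / track.fps


def lw_ratio_series(track: Track) -> np.ndarray:
    """Framewise length-to-width ratio of the bounding box."""
    width = track.width
    valid = ~np.isnan(width)
    if np.any(width[valid] <= 0):
        raise ValueError("non-positive box width")
    return track.length / width


# ---------------------------------------------------------------------------
# Per-bird pipeline
# ---------------------------------------------------------------------------

def extract_walk_features(
    records: pd.DataFrame,
    fps: float = DEFAULT_FPS,
    walk_direction: int = 1,
    max_gap: int = DEFAULT_MAX_GAP,
    window: int = DEFAULT_WINDOW,
    fit_against: str = "time",
) -> WalkFeatures:
    """Run the full feature pipeline for one bird's detection records."""
    track = build_track(records.sort_values("frame"), fps=fps)
    track = mask_backward_facing(track, walk_direction)
    track = interpolate_gaps(track, max_gap=max_gap)
    ct = completion_time(track)
    lw = lw_ratio_series(track)
    smoothed = smooth(track, window=window)
    fit = fit_trajectory(smoothed, against=fit_against)
    return WalkFeatures(
        bird_id=track.bird_id,
        lateral_oscillation=lateral_oscillation(fit),
        step_count=step_count(fit),
        completion_time=ct,
        lw_ratio_series=lw,
        n_frames=len(track),
        masked_fraction=track.masked_fraction,
        excluded=track.excluded or fit.short_track,
    )


def extract_features_table(
    detections: pd.DataFrame,
    fps: float = DEFAULT_FPS,
    walk_direction: int = 1,
    max_gap: int = DEFAULT_MAX_GAP,
    window: int = DEFAULT_WINDOW,
    fit_against: str = "time",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features for every bird in a detection table.

    Returns ``(features, lw_ratios)``: one row per bird with columns
    ``bird_id,osc_px,step_count,completion_s,n_frames,masked_frac,
    excluded_flag``, and a long-format per-frame length-width ratio table.
    """
    feat_rows, lw_rows = [], []
    for bird_id, group in detections.groupby("bird_id", sort=True):
        wf = extract_walk_features(
            group, fps=fps, walk_direction=walk_direction,
            max_gap=max_gap, window=window, fit_against=fit_against,
        )
        feat_rows.append({
            "bird_id": bird_id,
            "osc_px": wf.lateral_oscillation,
            "step_count": wf.step_count,
            "completion_s": wf.completion_time,
            "n_frames": wf.n_frames,
            "masked_frac": wf.masked_fraction,
            "excluded_flag": wf.excluded,
        })
        for i, r in enumerate(wf.lw_ratio_series):
            lw_rows.append({"bird_id": bird_id, "frame_offset": i, "lw_ratio": r})
    return pd.DataFrame(feat_rows), pd.DataFrame(lw_rows)
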