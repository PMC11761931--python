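"""Synthetic walkway data with the statistical structure the analysis assumes.

Emulates an individual walkway test: a top-view camera at 11 frames/s
records one broiler at a time traversing a ~3 m corridor. Each simulated
bird walks with a gait-class-dependent speed and pausing behaviour, while
its bounding-box centre oscillates laterally around a smooth (cubic) drift
as a sinusoid — two residual-trajectory crossings per stride — plus
Gaussian detection noise. The head keypoint sits forward of the centre
except on occasional backward-facing frames, and a small fraction of
frames goes missing, exercising the masking / interpolation stages with
known ground truth.

Per-gait-class walk parameters default to values calibrated so that the
population means of the extracted features (oscillation in px, step
count, completion time in s) land near the study-scale class means; body
weight and the leg-health scores (hock burn, footpad dermatitis) are
drawn per class, with leg-health classes independent of gait class (the
null the study observed).

The module also renders the two calibration fixtures the geometry stage
needs: corridor frames with walls at a known rotation, and checkerboard
views under known camera intrinsics and lens distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import CameraModel, undistort_normalized

GS_LEVELS = ["GS1", "GS2", "GS3+"]


@dataclass
class GSClassParams:
    """Walk-parameter distributions for one gait-score class.

    ``completion_mean_s`` and ``step_mean`` are the class targets for the
    extracted features; the stride frequency follows as
    steps / (2 * completion) crossings per stride pair. Pauses freeze the
    longitudinal coordinate while frames keep being emitted, so a long
    completion time may reflect slow walking, sitting, or both.
    """

    completion_mean_s: float
    completion_sd_s: float
    step_mean: float
    osc_mean_px: float
    osc_sd_px: float = 1.5
    step_freq_sd_hz: float = 0.05
    pause_prob: float = 0.0
    pause_len: int = 5
    noise_sd: float = 1.0
    drift_scale: tuple[float, float, float] = (20.0, 30.0, 30.0)
    weight_mean_g: float = 2300.0
    weight_sd_g: float = 235.0

    @property
    def step_freq_hz(self) -> float:
        """Lateral oscillation frequency (cycles/s): two crossings/cycle."""
        return self.step_mean / (2.0 * self.completion_mean_s)


def _default_class_params() -> dict[str, GSClassParams]:
    return {
        "GS1": GSClassParams(completion_mean_s=7.0, completion_sd_s=1.1,
                             step_mean=12.6, osc_mean_px=9.3,
                             pause_prob=0.005, pause_len=5,
                             weight_mean_g=2235.0),
        "GS2": GSClassParams(completion_mean_s=8.8, completion_sd_s=1.4,
                             step_mean=14.7, osc_mean_px=10.7,
                             pause_prob=0.015, pause_len=8,
                             weight_mean_g=2350.0),
        "GS3+": GSClassParams(completion_mean_s=21.6, completion_sd_s=3.2,
                              step_mean=22.4, osc_mean_px=10.9,
                              pause_prob=0.06, pause_len=15,
                              weight_mean_g=2480.0),
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic walkway population."""

    seed: int = 0
    fps: float = 11.0
    corridor_length_px: float = 1500.0
    class_probs: tuple[float, float, float] = (0.602, 0.322, 0.076)
    class_params: dict[str, GSClassParams] = field(default_factory=_default_class_params)
    backward_facing_prob: float = 0.0011
    missing_prob: float = 0.01
    hb1_prob: float = 0.076
    fpd_probs: tuple[float, float, float] = (0.534, 0.339, 0.127)
    lateral_center_px: float = 200.0
    box_length_mean_px: float = 115.0
    box_length_sd_px: float = 8.0
    lw_ratio_mean: float = 1.5
    lw_ratio_sd: float = 0.1

    def __post_init__(self):
        probs = np.asarray(self.class_probs, float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("class_probs must lie in [0,1] and sum to 1")
        for p in (self.backward_facing_prob, self.missing_prob, self.hb1_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        fpd = np.asarray(self.fpd_probs, float)
        if (fpd < 0).any() or abs(fpd.sum() - 1) > 1e-9:
            raise ValueError("fpd_probs must lie in [0,1] and sum to 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.corridor_length_px <= 0:
            raise ValueError("corridor_length_px must be positive")
        for cp in self.class_params.values():
            if cp.osc_mean_px < 0:
                raise ValueError("osc_amplitude must be >= 0")
            if not 0 <= cp.pause_prob <= 1:
                raise ValueError("pause_prob must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        data = {
            **{k: v for k, v in self.__dict__.items() if k != "class_params"},
            "class_params": {k: vars(v) for k, v in self.class_params.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(data), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "class_params" in data:
            data["class_params"] = {
                k: GSClassParams(**{kk: tuple(vv) if isinstance(vv, list) else vv
                                    for kk, vv in v.items()})
                for k, v in data["class_params"].items()
            }
        for key in ("class_probs", "fpd_probs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class BirdWalkParams:
    """Realized walk parameters of one bird."""

    bird_id: str
    fps: float
    corridor_length_px: float
    speed_px_per_frame: float
    osc_amplitude_px: float      # sinusoid amplitude A (px)
    osc_freq_hz: float
    phase_rad: float
    drift_coeffs: tuple[float, ...]  # cubic drift over normalized progress
    noise_sd: float
    pause_prob: float
    pause_len: int
    backward_facing_prob: float
    missing_prob: float
    lateral_center_px: float
    box_length_px: float
    box_width_px: float
    expected_frames: int


@dataclass
class GroundTruth:
    bird_id: str
    true_osc_amplitude: float
    true_crossings: int
    true_duration: float
    true_gs_class: str = ""
    true_hb_class: str = ""
    true_fpd_class: str = ""


MAX_WALK_FRAMES = 50_000


def _sign_changes(series: np.ndarray) -> int:
    s = np.sign(series)
    nz = np.flatnonzero(s)
    if len(nz) == 0:
        return 0
    s[: nz[0]] = s[nz[0]]
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return int(np.sum(s[1:] != s[:-1]))


def moving_average_gain(freq_hz: float, fps: float, window: int = 3) -> float:
    """Amplitude gain of a centred moving average on a sinusoid."""
    w = 2 * np.pi * freq_hz / fps
    return (1 + 2 * np.cos(w)) / window


def simulate_track(params: BirdWalkParams, seed: int | np.random.Generator = 0
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one bird's traversal as per-frame detection records.

    The longitudinal coordinate accumulates speed (frozen during pauses)
    until the corridor length is crossed; the lateral coordinate is cubic
    drift + A sin(2 pi f t / fps + phase) + Gaussian noise. Raises
    ``RuntimeError`` instead of hanging when the walk cannot terminate
    (non-positive speed and/or permanent pausing).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs = []
    x = 0.0
    pause_remaining = 0
    while x < params.corridor_length_px:
        xs.append(x)
        if len(xs) > MAX_WALK_FRAMES:
            raise RuntimeError(
                f"bird {params.bird_id}: walk does not terminate "
                f"(speed={params.speed_px_per_frame}, pause_prob={params.pause_prob})"
            )
        if pause_remaining > 0:
            pause_remaining -= 1
        elif params.pause_prob > 0 and rng.random() < params.pause_prob:
            pause_remaining = params.pause_len
        else:
            x += params.speed_px_per_frame

    xs = np.asarray(xs)
    n = len(xs)
    t = np.arange(n, dtype=float)
    tau = t / max(params.expected_frames, 1)
    drift = params.lateral_center_px + sum(
        c * tau ** (j + 1) for j, c in enumerate(params.drift_coeffs)
    )
    sinus = params.osc_amplitude_px * np.sin(
        2 * np.pi * params.osc_freq_hz * t / params.fps + params.phase_rad
    )
    noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    ys = drift + sinus + noise

    backward = rng.random(n) < params.backward_facing_prob
    head_offset = np.where(backward, -0.55, 0.55) * params.box_length_px
    half_l, half_w = params.box_length_px / 2, params.box_width_px / 2
    jitter = rng.normal(0, 0.5, (n, 2))
    records = pd.DataFrame({
        "bird_id": params.bird_id,
        "frame": np.arange(n),
        "conf": np.round(rng.uniform(0.85, 0.99, n), 4),
        "x_min": xs - half_l + jitter[:, 0],
        "y_min": ys - half_w + jitter[:, 1],
        "x_max": xs + half_l - jitter[:, 0],
        "y_max": ys + half_w - jitter[:, 1],
        "head_x": xs + head_offset,
        "head_y": ys + rng.normal(0, 1.0, n),
    })
    drop = rng.random(n) < params.missing_prob
    drop[0] = drop[-1] = False
    records = records.loc[~drop].reset_index(drop=True)

    truth = GroundTruth(
        bird_id=params.bird_id,
        true_osc_amplitude=params.osc_amplitude_px,
        true_crossings=_sign_changes(sinus),
        true_duration=n / params.fps,
    )
    return records, truth


def draw_bird_params(config: SimConfig, gs_class: str, bird_id: str,
                     rng: np.random.Generator) -> BirdWalkParams:
    """Draw one bird's walk parameters from its class distributions.

    The sinusoid amplitude is set to (pi/2) * class oscillation target,
    corrected for the window-3 moving-average gain at the bird's stride
    frequency, so that the mean absolute residual extracted downstream
    centres on the class target.
    """
    cp = config.class_params[gs_class]
    duration = max(2.0, rng.normal(cp.completion_mean_s, cp.completion_sd_s))
    freq = max(0.2, rng.normal(cp.step_freq_hz, cp.step_freq_sd_hz))
    osc_target = max(1.0, rng.normal(cp.osc_mean_px, cp.osc_sd_px))
    gain = moving_average_gain(freq, config.fps)
    pause_frac = cp.pause_prob * cp.pause_len / (1 + cp.pause_prob * cp.pause_len)
    speed = config.corridor_length_px / (duration * config.fps * (1 - pause_frac))
    box_l = max(60.0, rng.normal(config.box_length_mean_px, config.box_length_sd_px))
    ratio = max(1.1, rng.normal(config.lw_ratio_mean, config.lw_ratio_sd))
    return BirdWalkParams(
        bird_id=bird_id,
        fps=config.fps,
        corridor_length_px=config.corridor_length_px,
        speed_px_per_frame=speed,
        osc_amplitude_px=osc_target * np.pi / 2 / gain,
        osc_freq_hz=freq,
        phase_rad=rng.uniform(0, 2 * np.pi),
        drift_coeffs=tuple(rng.normal(0, s) for s in cp.drift_scale),
        noise_sd=cp.noise_sd,
        pause_prob=cp.pause_prob,
        pause_len=cp.pause_len,
        backward_facing_prob=config.backward_facing_prob,
        missing_prob=config.missing_prob,
        lateral_center_px=config.lateral_center_px,
        box_length_px=box_l,
        box_width_px=box_l / ratio,
        expected_frames=int(round(duration * config.fps)),
    )


def _draw_phenotype(config: SimConfig, gs_class: str, rng: np.random.Generator) -> dict:
    cp = config.class_params[gs_class]
    weight = max(800.0, rng.normal(cp.weight_mean_g, cp.weight_sd_g))
    gs_raw = {"GS1": 1, "GS2": 2}.get(gs_class, 3 if rng.random() < 7 / 9 else 4)
    hb_left = hb_right = 0
    if rng.random() < config.hb1_prob:
        # mild lesions only: at most score 2 on one hock
        score = 1 if rng.random() < 0.8 else 2
        if rng.random() < 0.5:
            hb_left = score
        else:
            hb_right = score
    fpd_class = rng.choice(3, p=np.asarray(config.fpd_probs))
    if fpd_class == 0:
        fpd_left = fpd_right = 0
    elif fpd_class == 1:
        fpd_left, fpd_right = [(1, 0), (1, 1), (2, 1), (0, 1)][rng.integers(4)]
    else:
        fpd_left, fpd_right = [(2, 2), (3, 2), (3, 3), (4, 2)][rng.integers(4)]
    return {
        "gs": gs_raw, "hb_left": hb_left, "hb_right": hb_right,
        "fpd_left": fpd_left, "fpd_right": fpd_right,
        "weight_g": round(weight, 1),
    }


def simulate_population(config: SimConfig, n: int = 118
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a walkway cohort: detections, phenotypes, and ground truth.

    Fully reproducible from ``config.seed``; n = 0 yields empty tables.
    """
    rng = np.random.default_rng(config.seed)
    detections, phenotypes, truths = [], [], []
    for i in range(n):
        bird_id = f"bird_{i + 1:04d}"
        gs_class = GS_LEVELS[rng.choice(3, p=np.asarray(config.class_probs))]
        params = draw_bird_params(config, gs_class, bird_id, rng)
        records, truth = simulate_track(params, rng)
        pheno = _draw_phenotype(config, gs_class, rng)
        truth.true_gs_class = gs_class
        truth.true_hb_class = "HB0" if pheno["hb_left"] == pheno["hb_right"] == 0 else "HB1"
        m = (pheno["fpd_left"] + pheno["fpd_right"]) / 2
        truth.true_fpd_class = ("FPD0" if m == 0 else "FPD1" if m < 2 else "FPD2")
        detections.append(records)
        phenotypes.append({"bird_id": bird_id, **pheno})
        truths.append(vars(truth))
    det = (pd.concat(detections, ignore_index=True) if detections
           else pd.DataFrame(columns=["bird_id", "frame", "conf", "x_min", "y_min",
                                      "x_max", "y_max", "head_x", "head_y"]))
    phe = pd.DataFrame(phenotypes, columns=["bird_id", "gs", "hb_left", "hb_right",
                                            "fpd_left", "fpd_right", "weight_g"])
    gt = pd.DataFrame(truths, columns=["bird_id", "true_osc_amplitude", "true_crossings",
                                       "true_duration", "true_gs_class",
                                       "true_hb_class", "true_fpd_class"])
    return det, phe, gt


# ---------------------------------------------------------------------------
# Image fixtures: corridor frames and checkerboard views
# ---------------------------------------------------------------------------

def render_corridor_frame(rotation_deg: float, size: tuple[int, int] = (360, 480)
                          ) -> np.ndarray:
    """Render a grayscale top view of the corridor at a known tilt.

    Two dark wall lines cross the frame at ``rotation_deg`` from
    horizontal (image convention: positive tilts slope downward to the
    right); the lower wall is the longest dark-light edge in the lower
    image half. Returns a uint8 array of the given (height, width).
    """
    if abs(rotation_deg) >= 45:
        raise ValueError("|rotation_deg| must be < 45")
    h, w = size
    if h < 120 or w < 160:
        raise ValueError("frame too small to contain the corridor")
    y, x = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2, (h - 1) / 2
    r = np.radians(rotation_deg)
    xr = np.cos(r) * (x - cx) + np.sin(r) * (y - cy)
    yr = -np.sin(r) * (x - cx) + np.cos(r) * (y - cy)

    half_width = 0.22 * h     # corridor half-width
    half_len = 0.46 * w
    wall_t = 5.0

    def soft(mask_dist):      # 1 inside, 0 outside, ~1 px anti-aliased ramp
        return np.clip(mask_dist + 0.5, 0.0, 1.0)

    img = np.full((h, w), 150.0)            # bedding outside the corridor
    inside = soft(half_width - np.abs(yr)) * soft(half_len - np.abs(xr))
    img = img * (1 - inside) + 205.0 * inside   # light corridor floor
    for d in (-half_width, half_width):
        wall = soft(wall_t / 2 - np.abs(yr - d)) * soft(half_len - np.abs(xr))
        img = img * (1 - wall) + 40.0 * wall
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_checkerboard_views(
    camera: CameraModel,
    n_views: int = 15,
    seed: int = 0,
    board_squares: int = 6,
    board_size_cm: float = 41.1,
    supersample: int = 2,
    identical_poses: bool = False,
) -> list[np.ndarray]:
    """Render synthetic views of the calibration checkerboard.

    A board of ``board_squares`` x ``board_squares`` squares (41.1 cm
    across, as printed for the pen-floor calibration) is posed at varied
    tilts and distances under the given intrinsics and distortion, and
    ray-traced with the full lens model (supersampled for anti-aliasing).
    ``identical_poses`` repeats a single pose — a degenerate set on which
    downstream calibration cannot succeed — and warns.
    """
    if n_views < 2:
        raise ValueError("need at least 2 views")
    if identical_poses:
        warnings.warn("identical poses are degenerate for calibration")
    rng = np.random.default_rng(seed)
    s = board_size_cm / board_squares
    half = board_size_cm / 2
    w, h = camera.width, camera.height
    if not (w and h):
        raise ValueError("camera model must declare image width and height")

    views = []
    pose = None
    for _ in range(n_views):
        if pose is None or not identical_poses:
            pose = _sample_pose(camera, half, rng)
        R, t = pose
        views.append(_render_board(camera, R, t, s, board_squares, half, supersample))
    return views


def _board_corners_visible(camera: CameraModel, R, t, half, margin=15) -> bool:
    corners = np.array([[-half, -half, 0], [half, -half, 0],
                        [half, half, 0], [-half, half, 0]], float)
    cam = corners @ R.T + t
    if (cam[:, 2] <= 1.0).any():
        return False
    xn, yn = cam[:, 0] / cam[:, 2], cam[:, 1] / cam[:, 2]
    from .geometry import distort_normalized

    xd, yd = distort_normalized(xn, yn, camera)
    u, v = camera.fx * xd + camera.cx, camera.fy * yd + camera.cy
    return bool((u > margin).all() and (u < camera.width - margin).all()
                and (v > margin).all() and (v < camera.height - margin).all())


def _sample_pose(camera: CameraModel, half: float, rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    for _ in range(200):
        angles = [rng.uniform(-25, 25), rng.uniform(-25, 25), rng.uniform(-12, 12)]
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        z0 = rng.uniform(1.4, 2.0) * half * 2 * camera.fx / camera.width
        t = np.array([rng.uniform(-0.08, 0.08) * z0,
                      rng.uniform(-0.08, 0.08) * z0, z0])
        if _board_corners_visible(camera, R, t, half):
            return R, t
    raise RuntimeError("could not sample a fully visible board pose")


def _render_board(camera: CameraModel, R, t, square, n_squares, half, supersample):
    w, h = camera.width, camera.height
    ss = supersample
    u = (np.arange(w * ss) + 0.5) / ss - 0.5
    v = (np.arange(h * ss) + 0.5) / ss - 0.5
    uu, vv = np.meshgrid(u, v)
    xd = (uu - camera.cx) / camera.fx
    yd = (vv - camera.cy) / camera.fy
    xn, yn = undistort_normalized(xd, yd, camera)
    # Intersect the ray lambda*(xn, yn, 1) with the board plane Z_board = 0.
    Rt = R.T
    d = np.stack([xn, yn, np.ones_like(xn)], axis=-1)
    db = d @ Rt.T
    tb = Rt @ t
    lam = tb[2] / db[..., 2]
    Xb = lam * db[..., 0] - tb[0]
    Yb = lam * db[..., 1] - tb[1]
    behind = lam <= 0
    i = np.floor((Xb + half) / square)
    j = np.floor((Yb + half) / square)
    on_board = (Xb >= -half) & (Xb <= half) & (Yb >= -half) & (Yb <= half) & ~behind
    checker = ((i + j) % 2 == 0)
    img = np.full(uu.shape, 0.60)
    img[on_board & checker] = 0.95
    img[on_board & ~checker] = 0.10
    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    return np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def write_population(det: pd.DataFrame, phe: pd.DataFrame, gt: pd.DataFrame,
                     out_dir) -> dict[str, str]:
    """Write the three simulation tables to ``out_dir``; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "detections": os.path.join(out_dir, "detections.csv"),
        "phenotypes": os.path.join(out_dir, "phenotypes.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.csv"),
    }
    det.to_csv(paths["detections"], index=False)
    phe.to_csv(paths["phenotypes"], index=False)
    gt.to_csv(paths["ground_truth"], index=False)
    return paths
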