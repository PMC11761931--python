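"""Camera calibration, undistortion, and walkway rotation alignment.

The walkway recordings are corrected in two geometric steps before any
tracking: (1) lens distortion is removed using intrinsics estimated from
checkerboard views (pinhole model with radial k1,k2,k3 and tangential
p1,p2 distortion, estimated by Zhang's homography method and refined by
full nonlinear reprojection minimisation), and (2) each frame is rotated
so the walkway runs horizontally, using the lower corridor wall found via
Canny edge detection and a probabilistic Hough transform. The rotation
angle is the Hough normal-form angle of that wall line minus 90 degrees.

Image convention throughout: grayscale arrays, origin top-left, x to the
right, y downward; angles of lines in normal form theta in [0, 180) with
theta = 90 for a horizontal line.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.feature import canny, corner_subpix, peak_local_max
from skimage.transform import estimate_transform, probabilistic_hough_line
from skimage.transform import rotate as _sk_rotate

DEFAULT_CANNY_LO = 50.0   # on the 0-255 grayscale range
DEFAULT_CANNY_HI = 150.0
ROTATION_FILL = 0.0       # constant fill for out-of-bounds pixels


class CalibrationError(RuntimeError):
    pass


class NoLineFoundError(RuntimeError):
    pass


@dataclass
class CameraModel:
    """Pinhole intrinsics with radial/tangential lens distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0
    width: int = 0
    height: int = 0
    reprojection_error: float = float("nan")

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.width and not (0 <= self.cx < self.width):
            raise ValueError("principal point cx outside the image")
        if self.height and not (0 <= self.cy < self.height):
            raise ValueError("principal point cy outside the image")

    @property
    def distortion(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class DetectedLine:
    """A Hough-detected line: normal form (rho, theta) plus the segment."""

    rho: float
    theta: float  # degrees, in [0, 180)
    endpoints: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        if not 0 <= self.theta < 180:
            raise ValueError("theta must lie in [0, 180)")


# ---------------------------------------------------------------------------
# Distortion model
# ---------------------------------------------------------------------------

def distort_normalized(xn: np.ndarray, yn: np.ndarray, camera: CameraModel):
    """Apply the lens distortion model to ideal normalized coordinates."""
    r2 = xn * xn + yn * yn
    radial = 1 + camera.k1 * r2 + camera.k2 * r2**2 + camera.k3 * r2**3
    xd = xn * radial + 2 * camera.p1 * xn * yn + camera.p2 * (r2 + 2 * xn * xn)
    yd = yn * radial + camera.p1 * (r2 + 2 * yn * yn) + 2 * camera.p2 * xn * yn
    return xd, yd


def undistort_normalized(xd: np.ndarray, yd: np.ndarray, camera: CameraModel,
                         iterations: int = 10):
    """Invert the distortion model by fixed-point iteration."""
    xn, yn = xd.copy(), yd.copy()
    for _ in range(iterations):
        r2 = xn * xn + yn * yn
        radial = 1 + camera.k1 * r2 + camera.k2 * r2**2 + camera.k3 * r2**3
        dx = 2 * camera.p1 * xn * yn + camera.p2 * (r2 + 2 * xn * xn)
        dy = camera.p1 * (r2 + 2 * yn * yn) + 2 * camera.p2 * xn * yn
        xn = (xd - dx) / radial
        yn = (yd - dy) / radial
    return xn, yn


def project_points(points_board: np.ndarray, rvec: np.ndarray, tvec: np.ndarray,
                   camera: CameraModel) -> np.ndarray:
    """Project planar board points (Z = 0) into pixel coordinates."""
    R = Rotation.from_rotvec(rvec).as_matrix()
    P = np.column_stack([points_board, np.zeros(len(points_board))])
    cam = P @ R.T + tvec
    xn, yn = cam[:, 0] / cam[:, 2], cam[:, 1] / cam[:, 2]
    xd, yd = distort_normalized(xn, yn, camera)
    return np.column_stack([camera.fx * xd + camera.cx, camera.fy * yd + camera.cy])


# ---------------------------------------------------------------------------
# Checkerboard corner detection
# ---------------------------------------------------------------------------

def find_checkerboard_corners(frame: np.ndarray, grid: tuple[int, int]) -> np.ndarray | None:
    """Locate and order the inner corners of a checkerboard.

    Returns an ``(rows*cols, 2)`` array of (x, y) pixel positions in
    row-major grid order, or ``None`` when the full grid cannot be found.
    Works for boards in roughly frontal view (in-plane rotation well below
    45 degrees); corners are localized to sub-pixel precision with a
    saddle-point refinement.
    """
    rows, cols = grid
    n_corners = rows * cols
    img = np.asarray(frame, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    # Checkerboard saddle response: quadrant kernel [[+,-],[-,+]].
    m = 4
    quad = np.ones((2 * m, 2 * m))
    quad[:m, m:] = -1
    quad[m:, :m] = -1
    resp = np.abs(ndimage.convolve(img, quad, mode="nearest"))
    peaks = peak_local_max(resp, min_distance=7, threshold_rel=0.35,
                           num_peaks=n_corners, exclude_border=5)
    if len(peaks) != n_corners:
        return None
    refined = corner_subpix(img, peaks, window_size=11)
    if np.isnan(refined).any():
        refined = np.where(np.isnan(refined), peaks.astype(float), refined)
    pts = refined[:, ::-1]  # (row, col) -> (x, y)

    # Order into a grid: take the 4 extreme corners, map the unit grid onto
    # them projectively, and match predictions to detections.
    s = pts.sum(axis=1)
    d = pts[:, 0] - pts[:, 1]
    corners4 = np.array([
        pts[np.argmin(s)],   # top-left
        pts[np.argmax(d)],   # top-right
        pts[np.argmax(s)],   # bottom-right
        pts[np.argmin(d)],   # bottom-left
    ])
    unit4 = np.array([[0, 0], [cols - 1, 0], [cols - 1, rows - 1], [0, rows - 1]], float)
    tf = estimate_transform("projective", unit4, corners4)
    gi, gj = np.meshgrid(np.arange(cols), np.arange(rows))
    pred = tf(np.column_stack([gi.ravel(), gj.ravel()]))
    ordered = np.empty_like(pred)
    used = set()
    for idx, p in enumerate(pred):
        dist = np.linalg.norm(pts - p, axis=1)
        j = int(np.argmin(dist))
        if j in used or dist[j] > 15:
            return None
        used.add(j)
        ordered[idx] = pts[j]
    return ordered


# ---------------------------------------------------------------------------
# Zhang calibration
# ---------------------------------------------------------------------------

def _zhang_intrinsics(homographies: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Closed-form intrinsics from >= 3 board homographies."""

    def v(h, i, j):
        return np.array([
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ])

    V = []
    for H in homographies:
        V.append(v(H, 0, 1))
        V.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.asarray(V)
    _, _, vt = np.linalg.svd(V)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    cy = (b12 * b13 - b11 * b23) / (b11 * b22 - b12**2)
    lam = b33 - (b13**2 + cy * (b12 * b13 - b11 * b23)) / b11
    fx = np.sqrt(lam / b11)
    fy = np.sqrt(lam * b11 / (b11 * b22 - b12**2))
    skew = -b12 * fx**2 * fy / lam
    cx = skew * cy / fy - b13 * fx**2 / lam
    if not (np.isfinite(fx) and np.isfinite(fy) and fx > 0 and fy > 0):
        raise CalibrationError("degenerate view geometry: closed-form intrinsics failed")
    return float(fx), float(fy), float(cx), float(cy)


def _initial_extrinsics(H: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1, 1, -1]) @ Vt
    return Rotation.from_matrix(R).as_rotvec(), t


def calibrate_camera(
    checkerboard_frames,
    grid: tuple[int, int] = (5, 5),
    square_size_cm: float = 41.1 / 6,
    min_frames: int = 10,
    radial_terms: int = 1,
) -> CameraModel:
    """Estimate intrinsics + distortion from checkerboard views.

    ``grid`` is the inner-corner layout (a board of six by six squares has
    5 x 5 inner corners). Raises :class:`CalibrationError`, naming the
    number of usable frames, when the pattern is found in fewer than
    ``min_frames`` views. ``radial_terms`` selects how many radial
    coefficients are estimated (1 -> k1 only, 2 -> +k2, 3 -> +k3); the
    default estimates k1 alone because over the radial range a centred
    board covers, r^4 and r^6 terms are nearly collinear with k1 and
    absorb corner-localization noise instead of modeling the lens.
    """
    frames = list(checkerboard_frames)
    if not frames:
        raise CalibrationError("calibration failed: pattern found in 0 frames")
    h, w = np.asarray(frames[0]).shape[:2]
    rows, cols = grid
    board = np.column_stack([
        np.tile(np.arange(cols), rows),
        np.repeat(np.arange(rows), cols),
    ]).astype(float) * square_size_cm

    image_points = []
    for frame in frames:
        pts = find_checkerboard_corners(frame, grid)
        if pts is not None:
            image_points.append(pts)
    if len(image_points) < min_frames:
        raise CalibrationError(
            f"calibration failed: pattern found in only {len(image_points)} "
            f"of {len(frames)} frames (need {min_frames})"
        )

    homographies = [
        np.asarray(estimate_transform("projective", board, pts).params)
        for pts in image_points
    ]
    fx, fy, cx, cy = _zhang_intrinsics(homographies)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1]])
    extrinsics = [_initial_extrinsics(H, K) for H in homographies]

    n_views = len(image_points)
    x0 = np.concatenate(
        [[fx, fy, cx, cy, 0, 0, 0, 0, 0]]
        + [np.concatenate([rv, tv]) for rv, tv in extrinsics]
    )
    obs = np.concatenate([p.ravel() for p in image_points])

    if radial_terms not in (1, 2, 3):
        raise ValueError("radial_terms must be 1, 2 or 3")

    def residuals(params):
        cam = CameraModel(fx=params[0], fy=params[1], cx=params[2], cy=params[3],
                          k1=params[4],
                          k2=params[5] if radial_terms >= 2 else 0.0,
                          p1=params[6], p2=params[7],
                          k3=params[8] if radial_terms >= 3 else 0.0)
        out = []
        for i in range(n_views):
            rv = params[9 + 6 * i: 12 + 6 * i]
            tv = params[12 + 6 * i: 15 + 6 * i]
            out.append(project_points(board, rv, tv, cam).ravel())
        return np.concatenate(out) - obs

    sol = least_squares(residuals, x0, method="lm", max_nfev=200)
    p = sol.x
    res = sol.fun.reshape(-1, 2)
    err = float(np.sqrt((res**2).sum(axis=1).mean()))  # RMS point error, px
    return CameraModel(
        fx=float(p[0]), fy=float(p[1]), cx=float(p[2]), cy=float(p[3]),
        k1=float(p[4]),
        k2=float(p[5]) if radial_terms >= 2 else 0.0,
        p1=float(p[6]), p2=float(p[7]),
        k3=float(p[8]) if radial_terms >= 3 else 0.0,
        width=w, height=h, reprojection_error=float(err),
    )


# ---------------------------------------------------------------------------
# Undistortion
# ---------------------------------------------------------------------------

def undistort_frame(frame: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Resample a frame so modeled lens distortion is removed.

    For each output (ideal) pixel the distorted source position is computed
    with the forward model and the input is sampled bilinearly.
    """
    img = np.asarray(frame, dtype=float)
    h, w = img.shape[:2]
    if camera.width and (w != camera.width or h != camera.height):
        raise ValueError(
            f"frame size {w}x{h} does not match camera model "
            f"{camera.width}x{camera.height}"
        )
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xn = (u - camera.cx) / camera.fx
    yn = (v - camera.cy) / camera.fy
    xd, yd = distort_normalized(xn, yn, camera)
    src_u = camera.fx * xd + camera.cx
    src_v = camera.fy * yd + camera.cy
    out = ndimage.map_coordinates(img, [src_v, src_u], order=1, mode="constant",
                                  cval=ROTATION_FILL)
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(np.asarray(frame).dtype)
    return out


# ---------------------------------------------------------------------------
# Walkway rotation
# ---------------------------------------------------------------------------

def detect_corridor_angle(
    frame: np.ndarray,
    canny_lo: float = DEFAULT_CANNY_LO,
    canny_hi: float = DEFAULT_CANNY_HI,
    min_length_frac: float = 0.4,
    line_gap: int = 5,
    hough_threshold: int = 10,
) -> DetectedLine:
    """Find the lower corridor-wall line and its normal-form angle.

    Canny edges feed a probabilistic Hough transform; among segments at
    least ``min_length_frac`` of the frame width long and within 45
    degrees of horizontal, the one whose midpoint lies lowest in the image
    is selected (the lower wall). The segment's orientation is refined by
    a total-least-squares fit to nearby edge pixels, then reported as
    theta = segment angle + 90 in [0, 180).
    """
    img = np.asarray(frame, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    edges = canny(img, sigma=1.5, low_threshold=canny_lo / 255.0,
                  high_threshold=canny_hi / 255.0)
    h, w = img.shape
    min_len = min_length_frac * w
    segments = probabilistic_hough_line(
        edges, threshold=hough_threshold, line_length=int(min_len),
        line_gap=line_gap, rng=0,
    )
    best = None
    best_key = None
    for (x0, y0), (x1, y1) in segments:
        dx, dy = x1 - x0, y1 - y0
        length = float(np.hypot(dx, dy))
        if length < min_len:
            continue
        phi = np.degrees(np.arctan2(dy, dx))
        phi = ((phi + 90) % 180) - 90  # direction angle in (-90, 90]
        if abs(phi) > 45:
            continue
        mid_y = (y0 + y1) / 2
        key = (mid_y, length)
        if best_key is None or key > best_key:
            best_key = key
            best = ((x0, y0), (x1, y1))
    if best is None:
        raise NoLineFoundError("no qualifying corridor wall line found")

    phi = _refine_segment_angle(edges, best)
    theta = (phi + 90.0) % 180.0
    (x0, y0), (x1, y1) = best
    rho = float(((x0 + x1) / 2) * np.cos(np.radians(theta))
                + ((y0 + y1) / 2) * np.sin(np.radians(theta)))
    return DetectedLine(rho=rho, theta=float(theta), endpoints=best)


def _refine_segment_angle(edges: np.ndarray, segment, band: float = 3.0) -> float:
    """Direction angle (degrees) of the edge pixels within ``band`` px of a
    Hough segment, from a total-least-squares (PCA) line fit."""
    (x0, y0), (x1, y1) = segment
    ys, xs = np.nonzero(edges)
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    # signed distance to the infinite line, plus along-segment clipping
    dist = np.abs(dy * (xs - x0) - dx * (ys - y0)) / norm
    tpar = ((xs - x0) * dx + (ys - y0) * dy) / norm**2
    sel = (dist <= band) & (tpar >= -0.02) & (tpar <= 1.02)
    if sel.sum() < 10:
        return float(np.degrees(np.arctan2(dy, dx)))
    pts = np.column_stack([xs[sel], ys[sel]]).astype(float)
    pts -= pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    vx, vy = vt[0]
    phi = np.degrees(np.arctan2(vy, vx))
    return ((phi + 90) % 180) - 90


def rotation_angle(theta: float) -> float:
    """Rotation needed to make a wall of normal-form angle theta horizontal:
    alpha = theta - 90 (degrees)."""
    if not 0 <= theta < 180:
        raise ValueError("theta must lie in [0, 180)")
    return theta - 90.0


def rotate_frame(frame: np.ndarray, alpha: float, fill: float | None = None) -> np.ndarray:
    """Rotate a frame about its centre to cancel a corridor tilt of
    ``alpha`` degrees (bilinear interpolation, constant fill).

    Positive alpha (wall sloping downward to the right in image
    coordinates) rotates the content so the wall becomes horizontal;
    rotate by alpha then -alpha is a pixelwise near-identity away from the
    borders. Out-of-bounds pixels are filled with ``fill`` (default: the
    frame's median intensity, which avoids creating spurious long border
    edges for the line detector).
    """
    if abs(alpha) >= 45:
        raise ValueError("|alpha| must be < 45 degrees")
    img = np.asarray(frame, dtype=float)
    if fill is None:
        fill = float(np.median(img))
    out = _sk_rotate(img, angle=alpha, resize=False, order=1,
                     mode="constant", cval=fill, preserve_range=True)
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(np.asarray(frame).dtype)
    return out


def align_frame(frame: np.ndarray, **kwargs) -> tuple[np.ndarray, float]:
    """Detect the corridor angle and rotate the frame level in one step."""
    line = detect_corridor_angle(frame, **kwargs)
    alpha = rotation_angle(line.theta)
    return rotate_frame(frame, alpha), alpha
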