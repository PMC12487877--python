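"""Multiview triangulation and pixel-to-millimeter error conversion.

Keypoints observed in two or more calibrated cameras are triangulated by the
direct linear transform (DLT): observations are undistorted to normalized
image coordinates, each view contributes two homogeneous linear constraints,
and the 3-D point is the smallest-singular-vector solution.  Per-view
reprojection errors, camera distances and angles from each optical axis are
reported so that pixel errors can be converted to physical units with the
pinhole small-angle relation

    error_mm = error_px * pixel_pitch * distance / focal_length

whose doubled 1-px footprint is the optical (Nyquist) resolution limit of
the rig.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import CameraModel


@dataclass
class TriangulatedPoint:
    position: np.ndarray  # (3,) world mm
    camera_ids: list[str]
    reprojection_errors_px: np.ndarray  # per view
    distances_mm: np.ndarray
    angles_deg: np.ndarray
    n_views: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# projection model (radial-tangential distortion)
# ---------------------------------------------------------------------------


def distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply [k1, k2, p1, p2, k3] distortion to normalized coordinates."""
    xy = np.asarray(xy, dtype=np.float64)
    k1, k2, p1, p2, k3 = np.asarray(dist, dtype=np.float64)
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def undistort_normalized(xy_dist: np.ndarray, dist: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Invert the distortion by fixed-point iteration (exact for dist = 0)."""
    xy_dist = np.asarray(xy_dist, dtype=np.float64)
    xy = xy_dist.copy()
    for _ in range(n_iter):
        delta = distort_normalized(xy, dist) - xy
        xy = xy_dist - delta
    return xy


def project_point(point_world: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project a world point (mm) to distorted pixel coordinates (x, y)."""
    Xc = camera.R @ np.asarray(point_world, dtype=np.float64) + camera.t
    if Xc[2] <= 0:
        raise ValueError("point is behind the camera")
    xy = Xc[:2] / Xc[2]
    xyd = distort_normalized(xy, camera.dist)
    uvw = camera.K @ np.array([xyd[0], xyd[1], 1.0])
    return uvw[:2]


def pixel_to_normalized(obs: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Undistorted normalized image coordinates of a pixel observation."""
    obs = np.asarray(obs, dtype=np.float64)
    Kinv = np.linalg.inv(camera.K)
    xyd = (Kinv @ np.array([obs[0], obs[1], 1.0]))[:2]
    return undistort_normalized(xyd, camera.dist)


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------


def triangulate(
    observations: list[tuple[str, float, float]],
    cameras: list[CameraModel],
    min_ray_angle_deg: float = 0.5,
) -> TriangulatedPoint:
    """DLT triangulation of one point from >= 2 pixel observations.

    Observations are undistorted before the linear solve.  Geometry is
    flagged degenerate when all pairs of viewing rays are closer to parallel
    than ``min_ray_angle_deg``.
    """
    if len(observations) < 2:
        raise ValueError("triangulation needs at least 2 views")
    cam_by_id = {c.camera_id: c for c in cameras}
    rows = []
    used: list[tuple[CameraModel, np.ndarray]] = []
    for cam_id, x, y in observations:
        cam = cam_by_id[cam_id]
        xy = pixel_to_normalized(np.array([x, y]), cam)
        P = np.hstack([cam.R, cam.t[:, None]])  # normalized projection
        rows.append(xy[0] * P[2] - P[0])
        rows.append(xy[1] * P[2] - P[1])
        used.append((cam, np.array([x, y])))
    A = np.asarray(rows)
    _, _, vt = np.linalg.svd(A)
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-12:
        raise ValueError("triangulation failed: point at infinity")
    X = Xh[:3] / Xh[3]

    # degenerate-geometry check: max pairwise ray angle
    dirs = []
    for cam, _ in used:
        v = X - cam.center
        n = np.linalg.norm(v)
        dirs.append(v / n if n > 0 else v)
    max_angle = 0.0
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            cosang = np.clip(abs(np.dot(dirs[i], dirs[j])), -1.0, 1.0)
            max_angle = max(max_angle, np.degrees(np.arccos(cosang)))
    degenerate = max_angle < min_ray_angle_deg

    reproj = np.array([np.linalg.norm(project_point(X, cam) - obs) for cam, obs in used])
    dist_angle = np.array([camera_distance_angle(X, cam) for cam, _ in used])
    return TriangulatedPoint(
        position=X,
        camera_ids=[cam.camera_id for cam, _ in used],
        reprojection_errors_px=reproj,
        distances_mm=dist_angle[:, 0],
        angles_deg=dist_angle[:, 1],
        n_views=len(used),
        degenerate=degenerate,
    )


def camera_distance_angle(point_world: np.ndarray, camera: CameraModel) -> tuple[float, float]:
    """Distance (mm) camera-center -> point and angle (deg) off the optical axis."""
    v = np.asarray(point_world, dtype=np.float64) - camera.center
    d = float(np.linalg.norm(v))
    if d == 0:
        raise ValueError("point coincides with the camera center; angle undefined")
    cosang = float(np.clip(np.dot(v / d, camera.optical_axis), -1.0, 1.0))
    return d, float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# physical-unit conversion
# ---------------------------------------------------------------------------


def pixels_to_mm(
    error_px: float, distance_mm: float, focal_length_mm: float = 8.0, pixel_pitch_um: float = 5.7
) -> float:
    """Object-plane size (mm) of a pixel-scale error at the given distance."""
    if distance_mm <= 0 or focal_length_mm <= 0 or pixel_pitch_um <= 0:
        raise ValueError("distance, focal length and pixel pitch must be positive")
    if error_px < 0:
        raise ValueError("error_px must be >= 0")
    return error_px * (pixel_pitch_um / 1000.0) * distance_mm / focal_length_mm


def mm_to_pixels(
    error_mm: float, distance_mm: float, focal_length_mm: float = 8.0, pixel_pitch_um: float = 5.7
) -> float:
    """Inverse of :func:`pixels_to_mm`."""
    one_px = pixels_to_mm(1.0, distance_mm, focal_length_mm, pixel_pitch_um)
    return error_mm / one_px


def nyquist_limit(
    pixel_pitch_um: float = 5.7, object_distance_mm: float = 304.8, focal_length_mm: float = 8.0
) -> float:
    """Optical resolution floor: twice the object-plane footprint of one pixel."""
    return 2.0 * pixels_to_mm(1.0, object_distance_mm, focal_length_mm, pixel_pitch_um)
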