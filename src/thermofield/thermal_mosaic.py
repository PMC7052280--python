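"""Thermal orthomosaic generation, viewing geometry and georeferencing.

Frames are orthoprojected onto a flat ground plane on a regular grid (cells
half-open ``[x, x+GSD) x [y, y+GSD)``, values referenced to cell centers)
with nearest-neighbor sampling from the source images.  Two blending modes
are supported:

``average``
    every mosaic pixel is the unweighted arithmetic mean of all frame pixels
    whose footprint covers it (wide, conical viewing geometry);
``disabled``
    every mosaic pixel comes from the single frame viewing that ground point
    closest to nadir (narrow, near-directional viewing geometry); ties go to
    the lowest frame id.

Per-pixel provenance (contributing-frame count, or winning frame id) is kept
so seamlines - boundaries where the source image changes - can be derived.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.feature import match_template, peak_local_max
from skimage.transform import SimilarityTransform

from .errors import FitError, GeometryError, InputError, ParameterError


def compute_gsd(altitude_m: float, fov_deg: float, n_pixels: int) -> float:
    """Ground sampling distance (m/px) of a nadir pinhole camera:
    ``2 * altitude * tan(fov / 2) / n_pixels``."""
    if fov_deg >= 180.0 or fov_deg <= 0.0:
        raise ParameterError(f"FOV {fov_deg} outside (0, 180)")
    if n_pixels <= 0 or altitude_m < 0:
        raise ParameterError("altitude must be >= 0 and pixel count positive")
    return 2.0 * altitude_m * math.tan(math.radians(fov_deg) / 2.0) / n_pixels


@dataclass(frozen=True)
class ViewGeometry:
    """Position of the camera as seen from a ground point: zenith from the
    vertical, azimuth clockwise from north."""

    zenith_deg: float
    azimuth_deg: float


def view_geometry(ground_point, pose) -> ViewGeometry:
    """Viewing geometry of camera ``pose`` (x, y, z[, yaw]) from a planar
    ground point (x, y)."""
    gx, gy = ground_point[0], ground_point[1]
    x, y, z = pose[0], pose[1], pose[2]
    if z <= 0:
        raise GeometryError("camera must be above the ground-point plane")
    dx, dy = x - gx, y - gy
    zen = math.degrees(math.atan(math.hypot(dx, dy) / z))
    az = math.degrees(math.atan2(dx, dy)) % 360.0
    return ViewGeometry(zenith_deg=zen, azimuth_deg=az)


@dataclass
class Orthomosaic:
    """Georeferenced temperature grid with per-pixel provenance.

    ``temperature[i, j]`` sits at planar center ``(x0 + (j+.5) gsd,
    y0 + (i+.5) gsd)``; NaN outside coverage.  ``provenance`` holds the
    contributing-frame count (mode ``average``) or the winning frame id, -1
    outside coverage (mode ``disabled``).
    """

    temperature: np.ndarray  # (ny, nx), degC, NaN = nodata
    gsd: float
    origin: tuple[float, float]  # planar coords of the (0, 0) cell corner
    provenance: np.ndarray
    blending_mode: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperature.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.temperature.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.gsd
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.gsd
        return xs, ys

    def xy_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Planar coordinates -> (row, col) of the containing cell."""
        j = np.floor((np.asarray(x) - self.origin[0]) / self.gsd).astype(np.int64)
        i = np.floor((np.asarray(y) - self.origin[1]) / self.gsd).astype(np.int64)
        return i, j

    def write_tiff(self, path) -> None:
        """32-bit float TIFF (NaN nodata) + JSON sidecar with the transform
        and a companion ``*.provenance.tif``."""
        path = str(path)
        tifffile.imwrite(path, self.temperature.astype(np.float32))
        tifffile.imwrite(path.replace(".tif", ".provenance.tif"),
                         self.provenance.astype(np.int32))
        with open(path + ".json", "w") as fh:
            json.dump({"gsd": self.gsd, "origin": list(self.origin),
                       "blending_mode": self.blending_mode}, fh)

    @classmethod
    def read_tiff(cls, path) -> "Orthomosaic":
        path = str(path)
        temp = tifffile.imread(path)
        prov = tifffile.imread(path.replace(".tif", ".provenance.tif"))
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(temperature=np.asarray(temp, dtype=np.float64), gsd=meta["gsd"],
                   origin=tuple(meta["origin"]), provenance=prov,
                   blending_mode=meta["blending_mode"])


def _frame_sample(frame, camera, xs, ys):
    """Nearest-neighbor sample of a frame at planar points (vectorized).

    Returns (values, valid mask, squared horizontal distance to the camera).
    """
    x, y, z, yaw = frame.pose
    dxw = xs - x
    dyw = ys - y
    rad = math.radians(yaw)
    c, s = math.cos(rad), math.sin(rad)
    # world -> camera frame (inverse rotation)
    tx = (dxw * c + dyw * s) / z
    ty = (-dxw * s + dyw * c) / z
    j = np.floor(tx * camera.focal_x + camera.n_x / 2.0).astype(np.int64)
    i = np.floor(ty * camera.focal_y + camera.n_y / 2.0).astype(np.int64)
    valid = (i >= 0) & (i < camera.n_y) & (j >= 0) & (j < camera.n_x)
    vals = np.full(xs.shape, np.nan)
    vals[valid] = frame.pixels[i[valid], j[valid]]
    return vals, valid, dxw * dxw + dyw * dyw


def build_orthomosaic(frames, camera, grid=None, mode: str = "average") -> Orthomosaic:
    """Mosaic overlapping nadir frames under one blending mode.

    ``grid`` is ``(xmin, ymin, xmax, ymax, gsd)``; by default the union of
    the frame footprints at the camera GSD for the flight altitude.
    """
    if not frames:
        raise InputError("empty frame list")
    if mode not in ("average", "disabled"):
        raise ParameterError(f"unknown blending mode {mode!r}")
    frames = sorted(frames, key=lambda f: f.frame_id)
    if grid is None:
        alt = frames[0].pose[2]
        gsd = compute_gsd(alt, camera.fov_x_deg, camera.n_x)
        fx, fy = camera.footprint(alt)
        half = math.hypot(fx, fy) / 2.0
        xs = [f.pose[0] for f in frames]
        ys = [f.pose[1] for f in frames]
        grid = (min(xs) - half, min(ys) - half, max(xs) + half, max(ys) + half, gsd)
    xmin, ymin, xmax, ymax, gsd = grid
    nx = max(int(math.ceil((xmax - xmin) / gsd)), 1)
    ny = max(int(math.ceil((ymax - ymin) / gsd)), 1)
    cx = xmin + (np.arange(nx) + 0.5) * gsd
    cy = ymin + (np.arange(ny) + 0.5) * gsd
    gx, gy = np.meshgrid(cx, cy)

    def window(f):
        """Mosaic index window covered by the frame footprint (+1 cell).
        Uses the footprint half-diagonal so it is valid for any yaw."""
        fx, fy = camera.footprint(f.pose[2])
        half = math.hypot(fx, fy) / 2.0
        j0 = max(int((f.pose[0] - half - xmin) / gsd) - 1, 0)
        j1 = min(int((f.pose[0] + half - xmin) / gsd) + 2, nx)
        i0 = max(int((f.pose[1] - half - ymin) / gsd) - 1, 0)
        i1 = min(int((f.pose[1] + half - ymin) / gsd) + 2, ny)
        return i0, i1, j0, j1

    if mode == "average":
        acc = np.zeros((ny, nx))
        cnt = np.zeros((ny, nx), dtype=np.int64)
        for f in frames:
            i0, i1, j0, j1 = window(f)
            if i0 >= i1 or j0 >= j1:
                continue
            sub = np.s_[i0:i1, j0:j1]
            vals, valid, _ = _frame_sample(f, camera, gx[sub], gy[sub])
            acc[sub][valid] += vals[valid]
            cnt[sub][valid] += 1
        with np.errstate(invalid="ignore"):
            temp = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        prov = cnt
    else:
        temp = np.full((ny, nx), np.nan)
        best = np.full((ny, nx), np.inf)
        prov = np.full((ny, nx), -1, dtype=np.int64)
        for f in frames:
            i0, i1, j0, j1 = window(f)
            if i0 >= i1 or j0 >= j1:
                continue
            sub = np.s_[i0:i1, j0:j1]
            vals, valid, d2 = _frame_sample(f, camera, gx[sub], gy[sub])
            better = valid & (d2 < best[sub])  # strict: ties keep the lower id
            temp[sub][better] = vals[better]
            best[sub][better] = d2[better]
            prov[sub][better] = f.frame_id
    if not np.any(np.isfinite(temp)):
        warnings.warn("mosaic grid lies outside all frame footprints; all-NaN mosaic")
    return Orthomosaic(temperature=temp, gsd=gsd, origin=(xmin, ymin),
                       provenance=prov, blending_mode=mode)


def seamline_mask(mosaic: Orthomosaic) -> np.ndarray:
    """Boolean raster marking pixels whose winning frame differs from a
    neighbor (mode ``disabled`` provenance changes)."""
    p = mosaic.provenance
    mask = np.zeros(p.shape, dtype=bool)
    mask[:, 1:] |= (p[:, 1:] != p[:, :-1]) & (p[:, 1:] >= 0) & (p[:, :-1] >= 0)
    mask[1:, :] |= (p[1:, :] != p[:-1, :]) & (p[1:, :] >= 0) & (p[:-1, :] >= 0)
    return mask


# ---------------------------------------------------------------------------
# GCP detection and georeferencing


@dataclass
class GeorefResult:
    """Similarity-transform fit of detected to true GCP coordinates."""

    residuals_m: np.ndarray  # (n, 2) residual vectors in the true frame
    rmse_m: float
    shift: tuple[float, float]
    rotation_deg: float
    scale: float

    @property
    def rmse_cm(self) -> float:
        return self.rmse_m * 100.0


def georeference(detected: np.ndarray, true: np.ndarray) -> GeorefResult:
    """Least-squares similarity transform (shift, rotation, scale) mapping
    detected GCP positions onto their surveyed coordinates."""
    detected = np.asarray(detected, dtype=float)
    true = np.asarray(true, dtype=float)
    if detected.shape != true.shape or detected.ndim != 2 or detected.shape[1] != 2:
        raise InputError("detected/true must be matching (n, 2) arrays")
    if len(detected) < 3:
        raise FitError("need at least 3 GCP pairs")
    if np.linalg.matrix_rank(detected - detected.mean(axis=0)) < 2:
        raise FitError("GCPs are collinear")
    tf = SimilarityTransform.from_estimate(detected, true)
    if not tf:
        raise FitError("similarity transform estimation failed")
    resid = tf(detected) - true
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return GeorefResult(
        residuals_m=resid,
        rmse_m=rmse,
        shift=(float(tf.translation[0]), float(tf.translation[1])),
        rotation_deg=math.degrees(float(tf.rotation)),
        scale=float(tf.scale),
    )


def gcp_template(gsd: float, plate_size_m: float = 0.5) -> np.ndarray:
    """Cross-target template at mosaic resolution: warm where the two
    opposing triangles sit (|dy| <= |dx| within the plate), cool elsewhere."""
    n = int(round(plate_size_m / gsd))
    if n < 3:
        raise ParameterError(
            f"GCP plate spans only {n} px at GSD {gsd:.3f} m; detection needs >= 3"
        )
    u = (np.arange(n) + 0.5) * gsd - plate_size_m / 2.0
    ux, uy = np.meshgrid(u, u)
    return (np.abs(uy) <= np.abs(ux)).astype(float)


def detect_gcps(
    mosaic: Orthomosaic,
    plate_size_m: float = 0.5,
    threshold: float = 0.6,
    max_targets: int | None = None,
) -> np.ndarray:
    """Detect cross-shaped thermal targets by normalized cross-correlation.

    Returns an (n, 2) array of planar target centers, refined to subpixel
    precision by a quadratic fit around each correlation peak.  An empty
    array (with a warning) when nothing matches.
    """
    templ = gcp_template(mosaic.gsd, plate_size_m)
    img = mosaic.temperature.copy()
    fin = np.isfinite(img)
    if not fin.any():
        warnings.warn("all-NaN mosaic: no GCPs detected")
        return np.empty((0, 2))
    img[~fin] = np.nanmedian(img)
    corr = match_template(img, templ, pad_input=True)
    min_dist = max(templ.shape[0], 3)
    peaks = peak_local_max(corr, min_distance=min_dist, threshold_abs=threshold,
                           num_peaks=max_targets or np.inf)
    if len(peaks) == 0:
        warnings.warn("no GCP template matches above threshold")
        return np.empty((0, 2))
    pts = []
    ny, nx = corr.shape
    for pi, pj in peaks:
        di = dj = 0.0
        if 0 < pi < ny - 1:
            c0, c1, c2 = corr[pi - 1, pj], corr[pi, pj], corr[pi + 1, pj]
            den = c0 - 2 * c1 + c2
            if den < 0:
                di = float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))
        if 0 < pj < nx - 1:
            c0, c1, c2 = corr[pi, pj - 1], corr[pi, pj], corr[pi, pj + 1]
            den = c0 - 2 * c1 + c2
            if den < 0:
                dj = float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))
        x = mosaic.origin[0] + (pj + dj + 0.5) * mosaic.gsd
        y = mosaic.origin[1] + (pi + di + 0.5) * mosaic.gsd
        pts.append((x, y))
    return np.array(pts)
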