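"""Per-plot canopy temperature extraction and viewing-geometry summaries.

Canopy temperature (CT) of a plot is the median of all mosaic pixels whose
centers fall inside the plot polygon after a 50 cm inward buffer (edge
effects from paths and border rows are excluded).  CT is normalized to the
ambient air temperature at 2 m as ``delta_t = t_c - t_a``, which makes
flights on different days comparable.

For anisotropy diagnostics, every (plot, frame) pair in which the buffered
plot is fully visible yields one apparent-temperature record together with
the viewing geometry of the camera as seen from the plot center; records are
binned over (view zenith, view azimuth) and the azimuthal first harmonic of
the bin means estimates the direction of the principal-plane gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import DegeneratePolygonError, InputError, ParameterError
from .scene_sim import CameraModel, SunGeometry, ThermalFrame
from .thermal_mosaic import Orthomosaic, view_geometry
from .trial_design import TrialDesign

#: columns of a plot-CT table
PLOT_CT_COLUMNS = ["plot_id", "flight_id", "timestamp", "t_c", "t_a", "delta_t", "n_pixels"]


def buffer_inward(polygon: Polygon, distance_m: float) -> Polygon:
    """Negative (inward) offset of a polygon ring.

    Raises :class:`DegeneratePolygonError` when the buffer consumes the
    polygon (e.g. 50 cm on a 1.0 m-wide plot) instead of silently returning
    an empty geometry.
    """
    if distance_m < 0:
        raise ParameterError("buffer distance must be >= 0")
    if distance_m == 0:
        return polygon
    out = polygon.buffer(-distance_m, join_style="mitre")
    if out.is_empty or out.area <= 0:
        raise DegeneratePolygonError(
            f"inward buffer of {distance_m} m consumed the polygon "
            f"(bounds {polygon.bounds})"
        )
    return out


def _median_in_polygon(mosaic: Orthomosaic, poly: Polygon):
    """Median of mosaic pixels with centers inside ``poly``; NaN excluded."""
    x0, y0, x1, y1 = poly.bounds
    i0, j0 = mosaic.xy_to_index(x0, y0)
    i1, j1 = mosaic.xy_to_index(x1, y1)
    ny, nx = mosaic.shape
    i0, i1 = max(int(i0), 0), min(int(i1) + 1, ny)
    j0, j1 = max(int(j0), 0), min(int(j1) + 1, nx)
    if i0 >= i1 or j0 >= j1:
        return np.nan, 0
    xs = mosaic.origin[0] + (np.arange(j0, j1) + 0.5) * mosaic.gsd
    ys = mosaic.origin[1] + (np.arange(i0, i1) + 0.5) * mosaic.gsd
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    vals = mosaic.temperature[i0:i1, j0:j1][inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, 0
    return float(np.median(vals)), int(vals.size)


def extract_plot_ct(
    mosaic: Orthomosaic,
    design: TrialDesign,
    buffer_m: float = 0.5,
    flight_id: str | None = None,
    timestamp: float | None = None,
) -> pd.DataFrame:
    """Plot-median canopy temperature from an orthomosaic.

    Returns a table with ``PLOT_CT_COLUMNS`` (``t_a``/``delta_t`` NaN until
    :func:`normalize_delta_t` is applied).  Plots without usable pixels are
    flagged missing (``t_c`` NaN, ``n_pixels`` 0), never coerced to zero.
    """
    rows = []
    for p in design.plots:
        if p.polygon is None:
            raise InputError(f"plot {p.plot_id} has no polygon")
        if p.is_filler:
            continue
        t_c, n = _median_in_polygon(mosaic, buffer_inward(p.polygon, buffer_m))
        rows.append((p.plot_id, flight_id, timestamp, t_c, np.nan, np.nan, n))
    return pd.DataFrame(rows, columns=PLOT_CT_COLUMNS)


def normalize_delta_t(t_c, t_a):
    """Air-temperature normalization ``delta_t = t_c - t_a`` (exact)."""
    return np.asarray(t_c, dtype=float) - np.asarray(t_a, dtype=float)


def air_temp_at(weather: pd.DataFrame, timestamp) -> np.ndarray:
    """Air temperature at given times by linear interpolation of a weather
    series (columns ``timestamp``, ``air_temp_c``); constant extrapolation at
    the series ends."""
    w = weather.sort_values("timestamp")
    return np.interp(np.asarray(timestamp, dtype=float),
                     w["timestamp"].to_numpy(), w["air_temp_c"].to_numpy())


def apply_delta_t(
    ct: pd.DataFrame, weather: pd.DataFrame, per_frame: bool = True
) -> pd.DataFrame:
    """Fill ``t_a``/``delta_t`` of a plot-CT table from a weather series.

    ``per_frame=False`` uses the flight-mean air temperature for all plots
    (the fallback when acquisition timestamps are unavailable)."""
    out = ct.copy()
    if per_frame and out["timestamp"].notna().all():
        out["t_a"] = air_temp_at(weather, out["timestamp"].to_numpy())
    else:
        out["t_a"] = float(weather["air_temp_c"].mean())
    out["delta_t"] = normalize_delta_t(out["t_c"], out["t_a"])
    return out


# ---------------------------------------------------------------------------
# per-plot viewing geometry across frames


def plot_view_geometries(
    plot: "object",
    frames: list[ThermalFrame],
    camera: CameraModel,
    buffer_m: float = 0.5,
    statistic: str = "median",
) -> pd.DataFrame:
    """Apparent temperature of one plot from every frame that sees it.

    ``plot`` is a PlotRecord (with polygon) or a shapely polygon.  A frame
    contributes when its footprint contains the whole buffered plot; the
    record holds the frame id, the viewing geometry of the plot center and
    the median (or mean) of that frame's pixels inside the buffered plot.
    Returns an empty table when no frame sees the plot.
    """
    poly = plot if isinstance(plot, Polygon) else plot.polygon
    bp = buffer_inward(poly, buffer_m)
    bx0, by0, bx1, by1 = bp.bounds
    cx, cy = poly.centroid.x, poly.centroid.y
    agg = np.median if statistic == "median" else np.mean
    rows = []
    for f in sorted(frames, key=lambda f: f.frame_id):
        x, y, z, yaw = f.pose
        fx, fy = camera.footprint(z)
        ex, ey = (fx, fy) if yaw % 180 == 0 else (fy, fx)
        if not (x - ex / 2 <= bx0 and bx1 <= x + ex / 2
                and y - ey / 2 <= by0 and by1 <= y + ey / 2):
            continue
        from .thermal_mosaic import _frame_sample

        xs = np.arange(bx0, bx1, camera.footprint(z)[0] / camera.n_x / 2)
        ys = np.arange(by0, by1, camera.footprint(z)[1] / camera.n_y / 2)
        gx, gy = np.meshgrid(xs, ys)
        m = shapely.contains_xy(bp, gx.ravel(), gy.ravel())
        vals, valid, _ = _frame_sample(f, camera, gx.ravel()[m], gy.ravel()[m])
        vals = vals[valid & np.isfinite(vals)]
        if vals.size == 0:
            continue
        vg = view_geometry((cx, cy), f.pose)
        rows.append((f.frame_id, f.timestamp, vg.zenith_deg, vg.azimuth_deg,
                     float(agg(vals)), int(vals.size)))
    return pd.DataFrame(
        rows, columns=["frame_id", "timestamp", "zenith_deg", "azimuth_deg",
                       "t_apparent", "n_pixels"]
    )


def all_plot_view_geometries(
    design: TrialDesign,
    frames: list[ThermalFrame],
    camera: CameraModel,
    buffer_m: float = 0.5,
    statistic: str = "median",
) -> pd.DataFrame:
    """Viewing-geometry records for every (plot, frame) pair, vectorized.

    Requires the regular heading-0 plot grid produced by the design module:
    pixels are assigned to plots by grid arithmetic on the cell pitch, and
    the buffered plot is the cell rectangle inset by ``buffer_m``.
    """
    ox, oy = design.origin
    px, py = design.cell_pitch
    if buffer_m * 2 >= min(px, py):
        raise DegeneratePolygonError(f"buffer {buffer_m} m consumes {px}x{py} m cells")
    nr, nc = design.virtual_shape if design.virtual_shape else (
        design.rep_shape[0], design.rep_shape[1])
    occ = np.full((nr, nc), -1, dtype=np.int64)
    centers = {}
    for i, p in enumerate(design.plots):
        if p.is_filler:
            continue
        vr = p.virtual_row if p.virtual_row is not None else p.row
        vc = p.virtual_range if p.virtual_range is not None else p.range
        occ[vr - 1, vc - 1] = i
        centers[i] = (ox + (vc - 0.5) * px, oy + (vr - 0.5) * py)

    from .scene_sim import _pixel_ground_offsets

    agg = "median" if statistic == "median" else "mean"
    parts = []
    for f in sorted(frames, key=lambda f: f.frame_id):
        x, y, z, yaw = f.pose
        dxw, dyw, _, _ = _pixel_ground_offsets(camera, z, yaw)
        gx, gy = x + dxw, y + dyw
        ci = np.floor((gx - ox) / px).astype(np.int64)
        ri = np.floor((gy - oy) / py).astype(np.int64)
        inb = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
        pid = np.where(inb, occ[np.clip(ri, 0, nr - 1), np.clip(ci, 0, nc - 1)], -1)
        ux = (gx - ox) - ci * px
        uy = (gy - oy) - ri * py
        in_buf = (ux >= buffer_m) & (ux <= px - buffer_m) & (uy >= buffer_m) & (uy <= py - buffer_m)
        sel = (pid >= 0) & in_buf
        if not sel.any():
            continue
        s = pd.DataFrame({"plot": pid[sel], "t": f.pixels[sel].astype(np.float64)})
        g = s.groupby("plot")["t"].agg(agg)
        n = s.groupby("plot")["t"].size()
        # keep only plots whose buffered cell is fully inside the footprint
        xmin, xmax = gx.min(), gx.max()
        ymin, ymax = gy.min(), gy.max()
        for plot_i, t_val in g.items():
            pcx, pcy = centers[plot_i]
            if (pcx - px / 2 + buffer_m >= xmin and pcx + px / 2 - buffer_m <= xmax
                    and pcy - py / 2 + buffer_m >= ymin and pcy + py / 2 - buffer_m <= ymax):
                vg = view_geometry((pcx, pcy), f.pose)
                parts.append((design.plots[plot_i].plot_id, f.frame_id, f.timestamp,
                              vg.zenith_deg, vg.azimuth_deg, float(t_val),
                              int(n.loc[plot_i])))
    return pd.DataFrame(
        parts, columns=["plot_id", "frame_id", "timestamp", "zenith_deg",
                        "azimuth_deg", "t_apparent", "n_pixels"]
    )


# ---------------------------------------------------------------------------
# anisotropy summary


@dataclass
class AnisotropyMap:
    """Binned mean apparent temperature over (view zenith, view azimuth)."""

    table: pd.DataFrame  # zenith_bin, azimuth_bin, mean_t, n
    gradient_azimuth_deg: float  # direction of maximal apparent temperature
    gradient_amplitude_c: float  # first-harmonic amplitude
    zenith_bin_deg: float
    azimuth_bin_deg: float


def anisotropy_summary(
    records: pd.DataFrame,
    sun: SunGeometry | None = None,
    zenith_bin_deg: float = 2.0,
    azimuth_bin_deg: float = 30.0,
    min_zenith_deg: float = 2.0,
) -> AnisotropyMap:
    """Bin apparent-temperature records over viewing geometry and fit the
    azimuthal first harmonic.

    The harmonic ``b0 + b1 cos(az) + b2 sin(az)`` is fitted to the bin means
    (weighted by bin counts) over bins with zenith above ``min_zenith_deg``,
    where azimuth is meaningful; the fitted gradient azimuth ``atan2(b2,
    b1)`` points toward the warm (sun-side) direction of the principal
    plane.
    """
    if records.empty:
        raise InputError("no viewing-geometry records")
    df = records.copy()
    df["zenith_bin"] = (df["zenith_deg"] // zenith_bin_deg) * zenith_bin_deg
    df["azimuth_bin"] = (df["azimuth_deg"] // azimuth_bin_deg) * azimuth_bin_deg
    tab = (
        df.groupby(["zenith_bin", "azimuth_bin"])["t_apparent"]
        .agg(mean_t="mean", n="size")
        .reset_index()
    )
    fit = tab[tab["zenith_bin"] >= min_zenith_deg]
    if fit.empty:
        raise InputError("no off-nadir bins to fit the azimuthal harmonic")
    az = np.radians(fit["azimuth_bin"].to_numpy() + azimuth_bin_deg / 2.0)
    A = np.column_stack([np.ones_like(az), np.cos(az), np.sin(az)])
    w = np.sqrt(fit["n"].to_numpy(dtype=float))
    coef, *_ = np.linalg.lstsq(A * w[:, None], fit["mean_t"].to_numpy() * w, rcond=None)
    grad_az = float(np.degrees(np.arctan2(coef[2], coef[1])) % 360.0)
    amp = float(np.hypot(coef[1], coef[2]))
    return AnisotropyMap(
        table=tab,
        gradient_azimuth_deg=grad_az,
        gradient_amplitude_c=amp,
        zenith_bin_deg=zenith_bin_deg,
        azimuth_bin_deg=azimuth_bin_deg,
    )


def nadir_hotspot_contrast(aniso: AnisotropyMap, sun: SunGeometry,
                           zenith_range=(10.0, 12.0)) -> float:
    """Mean of the nadir bin minus the mean of same-zenith bins perpendicular
    to the solar principal plane (positive = hotspot present)."""
    tab = aniso.table
    nadir = tab[tab["zenith_bin"] == 0.0]
    if nadir.empty:
        raise InputError("no nadir bin")
    nadir_t = float(np.average(nadir["mean_t"], weights=nadir["n"]))
    perp1 = (sun.azimuth_deg + 90.0) % 360.0
    perp2 = (sun.azimuth_deg - 90.0) % 360.0
    sel = tab[(tab["zenith_bin"] >= zenith_range[0]) & (tab["zenith_bin"] < zenith_range[1])]
    bw = aniso.azimuth_bin_deg

    def _near(az_bin, target):
        center = az_bin + bw / 2.0
        d = np.abs((center - target + 180.0) % 360.0 - 180.0)
        return d <= bw
    m = sel[_near(sel["azimuth_bin"].to_numpy(), perp1)
            | _near(sel["azimuth_bin"].to_numpy(), perp2)]
    if m.empty:
        raise InputError("no perpendicular bins in the requested zenith range")
    return nadir_t - float(np.average(m["mean_t"], weights=m["n"]))
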