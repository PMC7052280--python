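"""Synthetic thermal scene generator for a UAV canopy-temperature campaign.

Simulates everything a real flight over a wheat trial would deliver, with
known ground truth: per-plot canopy temperatures composed of genotypic,
smooth-spatial, row and plot-noise effects; a warm-soil background; a
directional (anisotropic) apparent-temperature model with a gradient along
the solar principal plane and a nadir hotspot; ambient-temperature drift
during the flight; and nadir thermal camera frames rendered along a
lawnmower flight plan, including cross-patterned thermal ground-control
targets and NETD-level pixel noise.

The directional model mixes soil and canopy radiometric temperature by the
visible-soil fraction

    f_soil(theta_v, dphi) = (1 - cover) * exp(-k tan theta_v)
                            * (1 + a cos(dphi) sin(theta_v))

with ``theta_v`` the view zenith and ``dphi`` the view-minus-sun azimuth
difference.  ``exp(-k tan theta_v)`` is the gap fraction seen through a row
canopy (maximal at nadir - the hotspot); the ``a cos(dphi) sin(theta_v)``
term raises apparent temperature at sun-side (acute) view azimuths, giving
the principal-plane gradient.  ``a <= k`` keeps the hotspot at nadir.  The
defaults (k = a = 3, cover 0.70, soil 14 degC warmer than canopy) are
calibrated so that apparent temperature spans roughly 3.5 degC across a
25-degree field of view of view angles under the reference sun position
(azimuth 199 deg, zenith 25 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .trial_design import TrialDesign

DN_GAIN = 25.0  # DN per kelvin of the linear radiometric encoding
DN_OFFSET = 273.15  # degC -> K shift before encoding


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SunGeometry:
    """Solar position: azimuth clockwise from north, zenith from vertical."""

    azimuth_deg: float = 199.0
    zenith_deg: float = 25.0

    def __post_init__(self):
        if not 0.0 <= self.azimuth_deg < 360.0:
            raise ParameterError(f"sun azimuth {self.azimuth_deg} outside [0, 360)")
        if not 0.0 <= self.zenith_deg < 90.0:
            raise ParameterError(f"sun zenith {self.zenith_deg} outside [0, 90)")


@dataclass(frozen=True)
class AnisoParams:
    """Directional mixing parameters: gap-fraction decay ``k`` and
    principal-plane modulation amplitude ``a`` (dimensionless)."""

    k: float = 3.0
    a: float = 3.0


@dataclass(frozen=True)
class CameraModel:
    """Nadir-gimbal thermal camera (pinhole, no distortion).

    The image x axis carries ``n_x`` pixels over ``fov_x_deg``; NETD is the
    per-pixel Gaussian noise sd in degC.  ``downsample(f)`` keeps the FOV and
    divides the resolution (coarser ground sampling, same footprint).
    """

    fov_x_deg: float = 25.0
    fov_y_deg: float = 20.0
    n_x: int = 640
    n_y: int = 512
    netd_c: float = 0.05
    bias_c: float = 0.0

    def __post_init__(self):
        if self.fov_x_deg <= 0 or self.fov_y_deg <= 0:
            raise ParameterError("FOV must be positive")
        if self.n_x <= 0 or self.n_y <= 0:
            raise ParameterError("resolution must be positive")
        if self.netd_c < 0:
            raise ParameterError("NETD must be >= 0")

    @property
    def focal_x(self) -> float:
        return (self.n_x / 2.0) / math.tan(math.radians(self.fov_x_deg) / 2.0)

    @property
    def focal_y(self) -> float:
        return (self.n_y / 2.0) / math.tan(math.radians(self.fov_y_deg) / 2.0)

    def footprint(self, altitude: float) -> tuple[float, float]:
        """Ground footprint (x, y extents in m) at the given altitude."""
        return (
            2.0 * altitude * math.tan(math.radians(self.fov_x_deg) / 2.0),
            2.0 * altitude * math.tan(math.radians(self.fov_y_deg) / 2.0),
        )

    def downsample(self, factor: int) -> "CameraModel":
        return CameraModel(
            self.fov_x_deg,
            self.fov_y_deg,
            self.n_x // factor,
            self.n_y // factor,
            self.netd_c,
            self.bias_c,
        )


@dataclass
class GcpTarget:
    """Thermal ground-control target: warm cross (two opposing triangles) on
    a cool square plate."""

    gcp_id: int
    x: float
    y: float
    plate_size_m: float = 0.5
    plate_temp_c: float = 24.0
    cross_temp_c: float = 55.0


@dataclass
class GroundTruthParams:
    """Study conditions of the emulated trial (temperatures in degC)."""

    air_temp_c: float = 25.0
    canopy_minus_air_c: float = 8.0
    soil_contrast_c: float = 14.0  # soil warmer than mean canopy
    var_genotype: float = 0.6
    var_row: float = 0.1
    var_plot: float = 0.8
    surface_amplitude_c: float = 1.0
    cover_mean: float = 0.70
    cover_sd: float = 0.05
    drift_c_per_min: float = 0.0625  # 0.5 degC over an 8-min flight
    cloud_events: tuple = ()  # (t_start_s, t_end_s, contrast_drop_c)
    aniso: AnisoParams = dc_field(default_factory=AnisoParams)

    def __post_init__(self):
        for name in ("var_genotype", "var_row", "var_plot"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.cover_mean <= 1.0:
            raise ParameterError("cover_mean must be in [0, 1]")


@dataclass
class GroundTruth:
    """True (noise-free) state of the scene, aligned with ``design.plots``."""

    design: TrialDesign
    params: GroundTruthParams
    genotype_effects: dict[str, float]
    plot_canopy_temp: np.ndarray  # degC at t = 0, per plot
    plot_cover: np.ndarray  # fraction 0-1 per plot
    surface: np.ndarray  # smooth field s(r, c) per plot, degC
    row_effects: np.ndarray  # per virtual row (1-based index - 1)
    plot_noise: np.ndarray
    soil_temp_c: float
    gcps: list[GcpTarget]
    senescence: pd.DataFrame | None = None
    _occupancy: np.ndarray | None = None

    @property
    def h2_true(self) -> float:
        """Variance-ratio heritability of a 2-replicate plot mean:
        sigma_g^2 / (sigma_g^2 + sigma_p^2 / 2)."""
        p = self.params
        denom = p.var_genotype + p.var_plot / 2.0
        return p.var_genotype / denom if denom > 0 else 0.0

    def ambient_offset(self, t_s) -> np.ndarray | float:
        """Scene-wide temperature offset at flight time ``t_s`` (seconds):
        linear ambient drift minus any active cloud-event contrast drop."""
        t_s = np.asarray(t_s, dtype=float)
        off = self.params.drift_c_per_min * t_s / 60.0
        for t0, t1, drop in self.params.cloud_events:
            off = off - drop * ((t_s >= t0) & (t_s < t1))
        return off if off.ndim else float(off)

    def air_temp(self, t_s) -> np.ndarray | float:
        t_s = np.asarray(t_s, dtype=float)
        out = self.params.air_temp_c + self.params.drift_c_per_min * t_s / 60.0
        return out if out.ndim else float(out)

    def weather_series(self, t_max_s: float, step_s: float = 10.0) -> pd.DataFrame:
        ts = np.arange(0.0, t_max_s + step_s, step_s)
        return pd.DataFrame({"timestamp": ts, "air_temp_c": self.air_temp(ts)})

    @property
    def occupancy(self) -> np.ndarray:
        """(virtual_rows x ranges) array of plot indices, -1 where empty."""
        if self._occupancy is None:
            nr, nc = self.design.virtual_shape
            occ = np.full((nr, nc), -1, dtype=np.int64)
            for i, p in enumerate(self.design.plots):
                if not p.is_filler:
                    occ[p.virtual_row - 1, p.virtual_range - 1] = i
            self._occupancy = occ
        return self._occupancy

    def truth_frame(self) -> pd.DataFrame:
        df = self.design.to_frame()
        df["canopy_temp_c"] = self.plot_canopy_temp
        df["cover"] = self.plot_cover
        df["surface_c"] = self.surface
        df["plot_noise_c"] = self.plot_noise
        return df


@dataclass
class FlightPlan:
    """Lawnmower plan of nadir poses (x, y, z, yaw, timestamp)."""

    altitude_m: float
    speed_m_s: float
    frame_rate_hz: float
    track_spacing_m: float
    forward_overlap: float
    side_overlap: float
    poses: pd.DataFrame  # columns frame_id, x, y, z, yaw_deg, timestamp

    def write_csv(self, path) -> None:
        self.poses.to_csv(path, index=False)


@dataclass
class ThermalFrame:
    """One rendered thermal image in degC (float32)."""

    frame_id: int
    pixels: np.ndarray  # (n_y, n_x) degC
    pose: tuple[float, float, float, float]  # x, y, z, yaw_deg
    timestamp: float


# ---------------------------------------------------------------------------
# radiometric encoding


def encode_dn(temp_c: np.ndarray) -> np.ndarray:
    """degC -> 16-bit digital numbers of the linear radiometric model."""
    return np.round((np.asarray(temp_c) + DN_OFFSET) * DN_GAIN).astype(np.uint16)


def decode_dn(dn: np.ndarray) -> np.ndarray:
    """Digital numbers -> degC."""
    return np.asarray(dn, dtype=np.float64) / DN_GAIN - DN_OFFSET


# ---------------------------------------------------------------------------
# ground truth


def _smooth_surface(vr: np.ndarray, vc: np.ndarray, shape, amplitude, rng):
    """Smooth low-frequency field over the virtual grid with random phases."""
    nr, nc = shape
    ph = rng.uniform(0, 2 * np.pi, size=4)
    s = 0.5 * np.sin(2 * np.pi * vr / nr + ph[0]) + 0.5 * np.cos(
        2 * np.pi * vc / nc + ph[1]
    )
    s = s + 0.35 * np.sin(2 * np.pi * (1.7 * vr / nr + ph[2])) * np.cos(
        2 * np.pi * (1.3 * vc / nc + ph[3])
    )
    return amplitude * s


def default_gcp_layout(design: TrialDesign, margin_m: float = 3.0, n: int = 16,
                       **target_kw) -> list[GcpTarget]:
    """Evenly space ``n`` targets on a rectangle ``margin_m`` outside the
    bounding box of all plot polygons."""
    xs, ys = [], []
    for p in design.plots:
        if p.polygon is not None:
            x0, y0, x1, y1 = p.polygon.bounds
            xs += [x0, x1]
            ys += [y0, y1]
    xmin, xmax = min(xs) - margin_m, max(xs) + margin_m
    ymin, ymax = min(ys) - margin_m, max(ys) + margin_m
    w, h = xmax - xmin, ymax - ymin
    per = 2 * (w + h)
    gcps = []
    for i in range(n):
        d = per * i / n
        if d < w:
            x, y = xmin + d, ymin
        elif d < w + h:
            x, y = xmax, ymin + (d - w)
        elif d < 2 * w + h:
            x, y = xmax - (d - w - h), ymax
        else:
            x, y = xmin, ymax - (d - 2 * w - h)
        gcps.append(GcpTarget(gcp_id=i, x=x, y=y, **target_kw))
    return gcps


def simulate_ground_truth(
    design: TrialDesign,
    params: GroundTruthParams | None = None,
    seed: int = 0,
    gcps: list[GcpTarget] | None = None,
) -> GroundTruth:
    """Draw the true state of the field: per-plot canopy temperature

        T_i = baseline + g_geno(i) + s(r_i, c_i) + row(r_i) + eps_i

    with genotype, row and plot-noise effects drawn iid normal with the
    configured variances and ``s`` a smooth surface over the virtual grid.
    Reproducible for a fixed seed.
    """
    if params is None:
        params = GroundTruthParams()
    if design.virtual_shape is None:
        raise ParameterError("design needs a virtual grid (build_virtual_grid)")
    rng = np.random.default_rng(seed)
    baseline = params.air_temp_c + params.canopy_minus_air_c

    genotypes = sorted({p.genotype_id for p in design.plots if not p.is_filler})
    g_eff = dict(
        zip(genotypes, math.sqrt(params.var_genotype) * rng.standard_normal(len(genotypes)))
    )
    nr, nc = design.virtual_shape
    row_eff = math.sqrt(params.var_row) * rng.standard_normal(nr)

    vr = np.array([p.virtual_row for p in design.plots], dtype=float)
    vc = np.array([p.virtual_range for p in design.plots], dtype=float)
    surface = _smooth_surface(vr, vc, (nr, nc), params.surface_amplitude_c, rng)
    noise = math.sqrt(params.var_plot) * rng.standard_normal(len(design.plots))
    cover = np.clip(
        rng.normal(params.cover_mean, params.cover_sd, size=len(design.plots)), 0.0, 1.0
    )
    temp = np.array(
        [
            baseline + g_eff.get(p.genotype_id, 0.0) + surface[i] + row_eff[int(vr[i]) - 1] + noise[i]
            for i, p in enumerate(design.plots)
        ]
    )
    if gcps is None and design.plots[0].polygon is not None:
        gcps = default_gcp_layout(design)
    return GroundTruth(
        design=design,
        params=params,
        genotype_effects=g_eff,
        plot_canopy_temp=temp,
        plot_cover=cover,
        surface=surface,
        row_effects=row_eff,
        plot_noise=noise,
        soil_temp_c=baseline + params.soil_contrast_c,
        gcps=gcps or [],
        senescence=None,
    )


def simulate_senescence(
    design: TrialDesign,
    dates: Sequence[float],
    seed: int = 0,
    onset_span: tuple[float, float] | None = None,
    ramp_days: float = 12.0,
) -> pd.DataFrame:
    """Genotype x date visual senescence scores (0 green ... 10 senescent).

    Each genotype gets an onset day uniform over ``onset_span`` (default: the
    span of ``dates``); scores ramp linearly from 0 to 10 over ``ramp_days``
    after onset, hence are monotone non-decreasing over dates.
    """
    rng = np.random.default_rng(seed)
    genotypes = sorted({p.genotype_id for p in design.plots if not p.is_filler})
    dates = np.asarray(sorted(dates), dtype=float)
    if onset_span is None:
        onset_span = (dates.min(), dates.max())
    onset = rng.uniform(onset_span[0], onset_span[1], size=len(genotypes))
    scores = np.clip(
        np.ceil((dates[None, :] - onset[:, None]) / ramp_days * 10.0), 0, 10
    ).astype(int)
    return pd.DataFrame(scores, index=pd.Index(genotypes, name="genotype_id"),
                        columns=dates)


# ---------------------------------------------------------------------------
# directional apparent temperature


def soil_fraction(cover, zenith_deg, azimuth_deg, sun: SunGeometry,
                  aniso: AnisoParams) -> np.ndarray:
    """Visible-soil fraction for a view geometry (vectorized)."""
    zenith = np.asarray(zenith_deg, dtype=float)
    if np.any(zenith >= 90.0) or np.any(zenith < 0.0):
        raise GeometryError("view zenith outside [0, 90)")
    theta = np.radians(zenith)
    dphi = np.radians(np.asarray(azimuth_deg, dtype=float) - sun.azimuth_deg)
    gap = 1.0 - np.asarray(cover, dtype=float)
    f = gap * np.exp(-aniso.k * np.tan(theta)) * (1.0 + aniso.a * np.cos(dphi) * np.sin(theta))
    return np.clip(f, 0.0, 1.0)


def apparent_temperature(
    t_canopy, t_soil, cover, zenith_deg, azimuth_deg,
    sun: SunGeometry | None = None, aniso: AnisoParams | None = None,
) -> np.ndarray:
    """Directional apparent temperature: soil/canopy mixture weighted by the
    visible-soil fraction.  Continuous in the view angles; equals the canopy
    temperature at full cover."""
    if sun is None:
        sun = SunGeometry()
    if aniso is None:
        aniso = AnisoParams()
    cover = np.asarray(cover, dtype=float)
    if np.any(cover < 0) or np.any(cover > 1):
        raise ParameterError("cover must be in [0, 1]")
    f = soil_fraction(cover, zenith_deg, azimuth_deg, sun, aniso)
    return f * np.asarray(t_soil, dtype=float) + (1.0 - f) * np.asarray(t_canopy, dtype=float)


# ---------------------------------------------------------------------------
# flight planning


def plan_flight(
    area: tuple[float, float, float, float],
    altitude_m: float = 80.0,
    min_side_overlap: float = 0.70,
    min_forward_overlap: float = 0.90,
    speed_m_s: float = 3.0,
    frame_rate_hz: float = 2.2,
    camera: CameraModel | None = None,
) -> FlightPlan:
    """Plan a lawnmower flight over ``area`` = (xmin, ymin, xmax, ymax).

    Tracks run along the y (row) axis with the camera's long image axis in
    the flight direction (yaw 90 deg), so the across-track footprint is set
    by the narrow FOV.  Track spacing and frame spacing are chosen so the
    realized overlaps meet the configured minima; poses extend half a
    footprint beyond the area on every side.
    """
    if camera is None:
        camera = CameraModel()
    if not (0.0 <= min_side_overlap < 1.0 and 0.0 <= min_forward_overlap < 1.0):
        raise ParameterError("overlaps must be in [0, 1)")
    if speed_m_s <= 0 or frame_rate_hz <= 0 or altitude_m <= 0:
        raise ParameterError("speed, frame rate and altitude must be positive")
    xmin, ymin, xmax, ymax = area
    fp_along, fp_across = camera.footprint(altitude_m)  # long axis along track
    step = speed_m_s / frame_rate_hz
    fwd = 1.0 - step / fp_along
    if fwd < min_forward_overlap:
        raise ParameterError(
            f"speed {speed_m_s} m/s at {frame_rate_hz} Hz gives forward overlap "
            f"{fwd:.2f} < required {min_forward_overlap}"
        )
    spacing = (1.0 - min_side_overlap) * fp_across
    if xmax <= xmin and ymax <= ymin:
        # degenerate zero-area field: one nadir pose covers it
        poses = pd.DataFrame(
            [(0, xmin, ymin, altitude_m, 90.0, 0.0)],
            columns=["frame_id", "x", "y", "z", "yaw_deg", "timestamp"],
        )
        return FlightPlan(
            altitude_m=altitude_m, speed_m_s=speed_m_s, frame_rate_hz=frame_rate_hz,
            track_spacing_m=spacing, forward_overlap=fwd, side_overlap=1.0,
            poses=poses,
        )
    width = max(xmax - xmin, 0.0)
    n_tracks = max(int(math.ceil(width / spacing)) + 1, 1)
    x0 = (xmin + xmax) / 2.0 - (n_tracks - 1) * spacing / 2.0
    y_lo, y_hi = ymin - fp_along / 2.0, ymax + fp_along / 2.0
    n_steps = max(int(math.ceil((y_hi - y_lo) / step)) + 1, 1)

    rows = []
    t = 0.0
    fid = 0
    for k in range(n_tracks):
        x = x0 + k * spacing
        ys = y_lo + step * np.arange(n_steps)
        if k % 2 == 1:
            ys = ys[::-1]
        for y in ys:
            rows.append((fid, x, float(y), altitude_m, 90.0, t))
            t += 1.0 / frame_rate_hz
            fid += 1
        t += spacing / speed_m_s  # transit to the next track
    poses = pd.DataFrame(rows, columns=["frame_id", "x", "y", "z", "yaw_deg", "timestamp"])
    realized_side = 1.0 - spacing / fp_across if n_tracks > 1 else 1.0
    return FlightPlan(
        altitude_m=altitude_m,
        speed_m_s=speed_m_s,
        frame_rate_hz=frame_rate_hz,
        track_spacing_m=spacing,
        forward_overlap=fwd,
        side_overlap=realized_side,
        poses=poses,
    )


# ---------------------------------------------------------------------------
# frame rendering


def _pixel_ground_offsets(camera: CameraModel, altitude: float, yaw_deg: float):
    """World-frame ground offsets of all pixel rays of a nadir camera."""
    jx = (np.arange(camera.n_x) + 0.5 - camera.n_x / 2.0) / camera.focal_x
    iy = (np.arange(camera.n_y) + 0.5 - camera.n_y / 2.0) / camera.focal_y
    tx, ty = np.meshgrid(jx, iy)  # tangent offsets in camera frame
    yaw = math.radians(yaw_deg)
    cx, sx = math.cos(yaw), math.sin(yaw)
    dxw = altitude * (tx * cx - ty * sx)
    dyw = altitude * (tx * sx + ty * cx)
    return dxw, dyw, tx, ty


def render_frame(
    truth: GroundTruth,
    pose: tuple[float, float, float, float],
    camera: CameraModel,
    sun: SunGeometry | None = None,
    time_s: float = 0.0,
    frame_id: int = 0,
    rng: np.random.Generator | None = None,
) -> ThermalFrame:
    """Render one nadir frame by intersecting every pixel ray with the flat
    ground plane.

    Sown-plot interiors get the directional apparent temperature for that
    pixel's individual view geometry; paths, the replicate gap and field
    margins get the soil temperature; GCP targets override the scene; the
    ambient drift is added scene-wide and Gaussian NETD noise on top.
    """
    if sun is None:
        sun = SunGeometry()
    x, y, z, yaw = pose
    if z <= 0:
        raise GeometryError("camera pose must be above the ground plane")
    design = truth.design
    dxw, dyw, tx, ty = _pixel_ground_offsets(camera, z, yaw)
    gx, gy = x + dxw, y + dyw
    zen = np.degrees(np.arctan(np.hypot(tx, ty)))
    # azimuth of the camera as seen from the ground point (clockwise from N)
    az = np.degrees(np.arctan2(-dxw, -dyw)) % 360.0

    ox, oy = design.origin
    px, py = design.cell_pitch
    ci = np.floor((gx - ox) / px).astype(np.int64)  # range index (0-based)
    ri = np.floor((gy - oy) / py).astype(np.int64)  # virtual row index
    occ = truth.occupancy
    nr, nc = occ.shape
    inside = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
    plot_idx = np.where(inside, occ[np.clip(ri, 0, nr - 1), np.clip(ci, 0, nc - 1)], -1)

    # within-cell position: sown rectangle centered in the cell
    sx_m, sy_m = design.sown_size
    mx, my = (px - sx_m) / 2.0, (py - sy_m) / 2.0
    ux = (gx - ox) - ci * px
    uy = (gy - oy) - ri * py
    in_sown = (ux >= mx) & (ux <= px - mx) & (uy >= my) & (uy <= py - my)
    on_plot = (plot_idx >= 0) & in_sown

    img = np.full((camera.n_y, camera.n_x), truth.soil_temp_c, dtype=np.float64)
    if np.any(on_plot):
        idx = plot_idx[on_plot]
        img[on_plot] = apparent_temperature(
            truth.plot_canopy_temp[idx],
            truth.soil_temp_c,
            truth.plot_cover[idx],
            zen[on_plot],
            az[on_plot],
            sun,
            truth.params.aniso,
        )
    for g in truth.gcps:
        h = g.plate_size_m / 2.0
        m = (np.abs(gx - g.x) <= h) & (np.abs(gy - g.y) <= h)
        if np.any(m):
            cross = np.abs(gy - g.y) <= np.abs(gx - g.x)  # two opposing triangles
            img[m & cross] = g.cross_temp_c
            img[m & ~cross] = g.plate_temp_c
    img += truth.ambient_offset(time_s) + camera.bias_c
    if rng is not None and camera.netd_c > 0:
        img += rng.normal(0.0, camera.netd_c, size=img.shape)
    return ThermalFrame(
        frame_id=frame_id, pixels=img.astype(np.float32), pose=(x, y, z, yaw),
        timestamp=time_s,
    )


def render_flight(
    truth: GroundTruth,
    plan: FlightPlan,
    camera: CameraModel,
    sun: SunGeometry | None = None,
    seed: int | None = 0,
) -> list[ThermalFrame]:
    """Render every pose of a flight plan; one child RNG stream per frame."""
    rng = np.random.default_rng(seed) if seed is not None else None
    frames = []
    for rec in plan.poses.itertuples(index=False):
        frames.append(
            render_frame(
                truth,
                (rec.x, rec.y, rec.z, rec.yaw_deg),
                camera,
                sun,
                time_s=rec.timestamp,
                frame_id=int(rec.frame_id),
                rng=rng,
            )
        )
    return frames
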