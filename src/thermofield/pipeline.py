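"""End-to-end orchestration of the simulation study.

One :class:`RunConfig` drives the whole chain: design generation -> ground
truth -> flight plan -> frame rendering -> orthomosaics under one or both
blending modes -> plot extraction and delta-T normalization -> spatial model
fits (genotypes random for heritability, fixed for BLUEs and corrected
values) -> blending-mode agreement.  All randomness derives from one master
seed (deterministic child streams per stage), so identical config + seed
give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import agreement_stats as ag
from . import plot_extraction as pe
from . import scene_sim as sc
from . import spatial_model as sm
from . import thermal_mosaic as tm
from . import trial_design as td
from .errors import ValidationError

logger = logging.getLogger("thermofield")

BLENDING_MODES = ("average", "disabled")


@dataclass
class RunConfig:
    """Serializable configuration of a full simulated campaign."""

    seed: int = 0
    # design
    n_test: int = 351
    check_ids: tuple[str, ...] = ("CH_CLARO", "SURETTA", "CH_NARA")
    rep_shape: tuple[int, int] = (21, 18)
    check_block_shape: tuple[int, int] = (7, 6)
    rep1_rows: tuple[int, int] = (1, 21)
    rep2_rows: tuple[int, int] = (54, 74)
    cell_pitch: tuple[float, float] = td.DEFAULT_CELL_PITCH
    sown_size: tuple[float, float] = td.DEFAULT_SOWN_SIZE
    # scene
    scene: sc.GroundTruthParams = field(default_factory=sc.GroundTruthParams)
    sun: sc.SunGeometry = field(default_factory=sc.SunGeometry)
    # flight + camera
    altitude_m: float = 80.0
    speed_m_s: float = 3.0
    frame_rate_hz: float = 2.2
    min_side_overlap: float = 0.70
    min_forward_overlap: float = 0.90
    camera_downsample: int = 4  # 640x512 -> 160x128 for desk-scale runs
    netd_c: float = 0.05
    # extraction + model
    modes: tuple[str, ...] = BLENDING_MODES
    buffer_m: float = 0.5
    response: str = "delta_t"
    spline_fraction: float = sm.DEFAULT_SPLINE_FRACTION

    def camera(self) -> sc.CameraModel:
        cam = sc.CameraModel(netd_c=self.netd_c)
        return cam.downsample(self.camera_downsample) if self.camera_downsample > 1 else cam

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "scene" in raw and isinstance(raw["scene"], dict):
            scn = dict(raw["scene"])
            if "aniso" in scn and isinstance(scn["aniso"], dict):
                scn["aniso"] = sc.AnisoParams(**scn["aniso"])
            if "cloud_events" in scn:
                scn["cloud_events"] = tuple(tuple(e) for e in scn["cloud_events"])
            raw["scene"] = sc.GroundTruthParams(**scn)
        if "sun" in raw and isinstance(raw["sun"], dict):
            raw["sun"] = sc.SunGeometry(**raw["sun"])
        for key in ("check_ids", "rep_shape", "check_block_shape", "rep1_rows",
                    "rep2_rows", "cell_pitch", "sown_size", "modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def child_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31 derived from the master."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class RunResult:
    """All artifacts of one simulated campaign."""

    config: RunConfig
    design: td.TrialDesign
    truth: sc.GroundTruth
    plan: sc.FlightPlan
    frames: list
    weather: pd.DataFrame
    mosaics: dict[str, tm.Orthomosaic]
    plot_ct: dict[str, pd.DataFrame]
    fits_random: dict[str, sm.SpatialFit]
    fits_fixed: dict[str, sm.SpatialFit]
    heritability: pd.DataFrame
    corrected: dict[str, pd.DataFrame]
    agreement: ag.BlandAltman | None
    regression: tuple | None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for mode in self.config.modes:
            h = sm.heritability(self.fits_random[mode])
            rows.append(
                (mode, h.h2, h.ed_genotype, h.n_genotypes, h.var_genotype,
                 h.var_residual, self.fits_random[mode].converged,
                 self.fits_random[mode].n_iter)
            )
        return pd.DataFrame(
            rows, columns=["blending_mode", "h2", "ed_genotype", "n_genotypes",
                           "var_genotype", "var_residual", "converged", "n_iter"],
        )


def run_simulation_study(config: RunConfig, outdir=None) -> RunResult:
    """Execute the full pipeline for one simulated flight.

    With ``outdir`` set, writes every table (CSV), the polygons (GeoJSON)
    and the mosaics (TIFF + sidecar) with fixed column order for
    reproducible diffs.
    """
    seeds = child_seeds(config.seed, 4)
    logger.info("derived stage seeds: design=%d truth=%d noise=%d", *seeds[:3])

    design = td.generate_design(
        n_test=config.n_test, check_ids=config.check_ids,
        rep_shape=config.rep_shape, check_block_shape=config.check_block_shape,
        seed=seeds[0], cell_pitch=config.cell_pitch, sown_size=config.sown_size,
    )
    td.build_virtual_grid(design, config.rep1_rows, config.rep2_rows)
    td.plot_polygons(design)

    truth = sc.simulate_ground_truth(design, config.scene, seed=seeds[1])
    camera = config.camera()
    bounds = [p.polygon.bounds for p in design.plots]
    area = (
        min(b[0] for b in bounds), min(b[1] for b in bounds),
        max(b[2] for b in bounds), max(b[3] for b in bounds),
    )
    plan = sc.plan_flight(
        area, altitude_m=config.altitude_m,
        min_side_overlap=config.min_side_overlap,
        min_forward_overlap=config.min_forward_overlap,
        speed_m_s=config.speed_m_s, frame_rate_hz=config.frame_rate_hz,
        camera=camera,
    )
    logger.info("flight: %d frames, overlaps fwd=%.2f side=%.2f",
                len(plan.poses), plan.forward_overlap, plan.side_overlap)
    frames = sc.render_flight(truth, plan, camera, sun=config.sun, seed=seeds[2])
    weather = truth.weather_series(plan.poses["timestamp"].max())

    mosaics, plot_ct, fits_r, fits_f, corrected = {}, {}, {}, {}, {}
    for mode in config.modes:
        mosaics[mode] = tm.build_orthomosaic(frames, camera, mode=mode)
        ct = pe.extract_plot_ct(mosaics[mode], design, buffer_m=config.buffer_m,
                                flight_id=mode)
        ct = pe.apply_delta_t(ct, weather, per_frame=False)
        plot_ct[mode] = ct
        data = sm.make_grid_data(ct, design.to_frame(), response=config.response)
        grid_shape = (config.rep2_rows[1], config.rep_shape[1])
        fits_r[mode] = sm.fit_spats(data, "random", fraction=config.spline_fraction,
                                    grid_shape=grid_shape)
        fits_f[mode] = sm.fit_spats(data, "fixed", fraction=config.spline_fraction,
                                    grid_shape=grid_shape)
        corrected[mode] = sm.corrected_values(fits_f[mode])
        logger.info("mode %s: knots=%s, REML iters r=%d f=%d, converged r=%s f=%s",
                    mode, fits_r[mode].basis.knot_counts, fits_r[mode].n_iter,
                    fits_f[mode].n_iter, fits_r[mode].converged,
                    fits_f[mode].converged)

    agreement = regression = None
    if set(BLENDING_MODES) <= set(config.modes):
        a = plot_ct["average"].set_index("plot_id")["delta_t"]
        b = plot_ct["disabled"].set_index("plot_id")["delta_t"]
        both = pd.concat([a, b], axis=1, keys=["avg", "dis"]).dropna()
        agreement = ag.bland_altman(both["avg"], both["dis"])
        regression = ag.mode_regression(both["avg"], both["dis"])

    rows = []
    for mode in config.modes:
        h = sm.heritability(fits_r[mode])
        rows.append((mode, h.h2, h.ed_genotype, h.n_genotypes,
                     h.var_genotype, h.var_residual))
    herit = pd.DataFrame(rows, columns=[
        "blending_mode", "h2", "ed_genotype", "n_genotypes",
        "var_genotype", "var_residual"])

    result = RunResult(
        config=config, design=design, truth=truth, plan=plan, frames=frames,
        weather=weather, mosaics=mosaics, plot_ct=plot_ct, fits_random=fits_r,
        fits_fixed=fits_f, heritability=herit, corrected=corrected,
        agreement=agreement, regression=regression,
    )
    if outdir is not None:
        write_run(result, outdir)
    return result


def write_run(result: RunResult, outdir) -> None:
    """Write all run artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    result.design.write_csv(out / "design.csv")
    result.design.write_geojson(out / "plots.geojson")
    result.truth.truth_frame().to_csv(out / "truth.csv", index=False)
    result.plan.write_csv(out / "poses.csv")
    result.weather.to_csv(out / "weather.csv", index=False)
    result.heritability.to_csv(out / "heritability.csv", index=False)
    for mode in result.config.modes:
        result.mosaics[mode].write_tiff(str(out / f"mosaic_{mode}.tif"))
        result.plot_ct[mode].to_csv(out / f"plot_ct_{mode}.csv", index=False)
        result.corrected[mode].to_csv(out / f"corrected_{mode}.csv", index=False)
        result.fits_random[mode].summary_frame().to_csv(
            out / f"fit_summary_{mode}.csv", index=False)
        pd.DataFrame({
            "genotype_id": result.fits_fixed[mode].genotype_effects.index,
            "blue": result.fits_fixed[mode].genotype_effects.to_numpy(),
            "blup": result.fits_random[mode].genotype_effects.reindex(
                result.fits_fixed[mode].genotype_effects.index).to_numpy(),
        }).to_csv(out / f"genotype_values_{mode}.csv", index=False)
        sm.surface_grid(result.fits_random[mode]).to_csv(
            out / f"surface_{mode}.csv", index=False)
    if result.agreement is not None:
        pd.DataFrame({
            "statistic": ["bias", "loa_low", "loa_high", "slope_diff_vs_mean",
                          "regression_intercept", "regression_slope",
                          "regression_r2"],
            "value": [result.agreement.bias, result.agreement.loa_low,
                      result.agreement.loa_high, result.agreement.slope,
                      *result.regression],
        }).to_csv(out / "agreement.csv", index=False)


# ---------------------------------------------------------------------------
# frame I/O (CLI plumbing)


def write_frames(frames, path_tif, path_csv) -> None:
    """Persist frames as a multi-page 16-bit DN TIFF + pose sidecar CSV."""
    tifffile.imwrite(path_tif, np.stack([sc.encode_dn(f.pixels) for f in frames]),
                     photometric="minisblack")
    pd.DataFrame(
        [(f.frame_id, *f.pose, f.timestamp) for f in frames],
        columns=["frame_id", "x", "y", "z", "yaw_deg", "timestamp"],
    ).to_csv(path_csv, index=False)


def read_frames(path_tif, path_csv) -> list[sc.ThermalFrame]:
    stack = tifffile.imread(path_tif)
    poses = pd.read_csv(path_csv)
    frames = []
    for k, rec in enumerate(poses.itertuples(index=False)):
        frames.append(sc.ThermalFrame(
            frame_id=int(rec.frame_id),
            pixels=sc.decode_dn(stack[k]).astype(np.float32),
            pose=(rec.x, rec.y, rec.z, rec.yaw_deg),
            timestamp=float(rec.timestamp),
        ))
    return frames


# ---------------------------------------------------------------------------
# real-input validation


DESIGN_COLUMNS = ["plot_id", "genotype_id", "replicate", "row", "range",
                  "virtual_row", "virtual_range"]
WEATHER_COLUMNS = ["timestamp", "air_temp_c"]


def validate_real_inputs(
    design_csv=None, polygons_geojson=None, weather_csv=None, mosaic_tiff=None,
    flight_window: tuple[float, float] | None = None,
) -> dict:
    """Schema-check a real dataset; raises :class:`ValidationError` listing
    every defect found, otherwise returns loaded handles."""
    defects: list[str] = []
    handles: dict = {}
    if design_csv is not None:
        p = Path(design_csv)
        if not p.exists():
            defects.append(f"design file missing: {p}")
        else:
            df = pd.read_csv(p)
            missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
            if missing:
                defects.append(f"design table lacks columns: {missing}")
            else:
                handles["design"] = df
    if polygons_geojson is not None:
        p = Path(polygons_geojson)
        if not p.exists():
            defects.append(f"polygon file missing: {p}")
        else:
            with open(p) as fh:
                gj = json.load(fh)
            feats = gj.get("features", [])
            if not feats:
                defects.append("polygon file has no features")
            else:
                for k, f in enumerate(feats):
                    props = f.get("properties", {})
                    if "genotype_id" not in props:
                        defects.append(
                            f"polygon feature {k} lacks 'genotype_id' property")
                        break
                handles["polygons"] = gj
    if weather_csv is not None:
        p = Path(weather_csv)
        if not p.exists():
            defects.append(f"weather file missing: {p}")
        else:
            w = pd.read_csv(p)
            missing = [c for c in WEATHER_COLUMNS if c not in w.columns]
            if missing:
                defects.append(f"weather series lacks columns: {missing}")
            elif flight_window is not None:
                lo, hi = w["timestamp"].min(), w["timestamp"].max()
                if flight_window[0] < lo or flight_window[1] > hi:
                    defects.append(
                        f"weather series [{lo}, {hi}] does not cover the flight "
                        f"window {flight_window} (interpolation range)")
                else:
                    handles["weather"] = w
            else:
                handles["weather"] = w
    if mosaic_tiff is not None:
        p = Path(mosaic_tiff)
        if not p.exists():
            defects.append(f"mosaic file missing: {p}")
        else:
            try:
                handles["mosaic"] = tm.Orthomosaic.read_tiff(str(p))
            except Exception as exc:  # noqa: BLE001 - report as defect
                defects.append(f"mosaic unreadable: {exc}")
    if defects:
        raise ValidationError(defects)
    return handles
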