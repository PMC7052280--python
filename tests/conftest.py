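"""Shared fixtures: a full default design and a small rendered scene.

Session-scoped so the (seconds-long) render happens once; tests must not
mutate fixture objects.
"""

import numpy as np
import pytest

from thermofield import scene_sim as sc
from thermofield import thermal_mosaic as tm
from thermofield import trial_design as td
from thermofield.pipeline import RunConfig


@pytest.fixture(scope="session")
def full_design():
    """Default 2-replicate augmented design with virtual grid and polygons."""
    d = td.generate_design(seed=11)
    td.build_virtual_grid(d)
    td.plot_polygons(d)
    return d


@pytest.fixture(scope="session")
def small_config():
    """Reduced campaign (9x6 replicates, 48 genotypes) for fast end-to-end
    runs; scene physics identical to the defaults."""
    return RunConfig(
        seed=5,
        n_test=45,
        rep_shape=(9, 6),
        check_block_shape=(3, 6),
        rep1_rows=(1, 9),
        rep2_rows=(20, 28),
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    """Design + truth + frames + camera of the reduced campaign."""
    cfg = small_config
    d = td.generate_design(
        n_test=cfg.n_test, check_ids=cfg.check_ids, rep_shape=cfg.rep_shape,
        check_block_shape=cfg.check_block_shape, seed=1,
    )
    td.build_virtual_grid(d, cfg.rep1_rows, cfg.rep2_rows)
    td.plot_polygons(d)
    truth = sc.simulate_ground_truth(d, cfg.scene, seed=2)
    cam = cfg.camera()
    b = np.array([p.polygon.bounds for p in d.plots])
    area = (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())
    plan = sc.plan_flight(area, camera=cam)
    frames = sc.render_flight(truth, plan, cam, seed=3)
    return {"design": d, "truth": truth, "camera": cam, "plan": plan,
            "frames": frames, "area": area}


@pytest.fixture(scope="session")
def small_mosaics(small_scene):
    return {
        mode: tm.build_orthomosaic(small_scene["frames"], small_scene["camera"],
                                   mode=mode)
        for mode in ("average", "disabled")
    }


def make_flat_truth(design, baseline=30.0, cover=1.0, contrast=0.0,
                    drift=0.0, gcps=()):
    """Deterministic degenerate ground truth (no random effects)."""
    params = sc.GroundTruthParams(
        air_temp_c=baseline, canopy_minus_air_c=0.0, soil_contrast_c=contrast,
        var_genotype=0.0, var_row=0.0, var_plot=0.0, surface_amplitude_c=0.0,
        cover_mean=cover, cover_sd=0.0, drift_c_per_min=drift,
    )
    truth = sc.simulate_ground_truth(design, params, seed=0, gcps=list(gcps))
    return truth
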