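# thermofield

UAV thermal phenotyping of crop canopy temperature, end to end: from
overlapping nadir thermal frames to spatially corrected, heritable genotype
values.

Canopy temperature (CT) is a proxy for transpiration and water use, and
breeders want to rank hundreds of small plots by it.  Two things make that
hard: when many overlapping thermal images are mosaicked, every ground
point is seen under many viewing geometries and apparent temperature is
strongly directional (anisotropic); and field trials carry spatial trends
and within-flight ambient drift that swamp genotypic differences.  This
package implements the full processing chain that addresses both, for
researchers in high-throughput field phenotyping and quantitative genetics:

* **Orthomosaic blending** -- mode `average` (each mosaic pixel is the mean
  of all covering images) vs mode `disabled` (pixel from the image viewing
  that point closest to nadir), with per-pixel provenance and seamline maps.
* **Viewing-geometry diagnostics** -- per-plot apparent temperature as a
  function of view zenith/azimuth, the principal-plane gradient direction
  and the nadir hotspot.
* **Plot extraction** -- median CT inside a 50 cm inward-buffered plot
  polygon, normalized by air temperature: dT = T_C - T_A.
* **Spatial correction and heritability** -- the mixed model
  Y = f(r, c) + Z_g c_g + Z_r c_r + eps on a 74 x 18 virtual grid, where
  f(r, c) is a PS-ANOVA tensor-product P-spline (spline points = 2/3 of the
  rows/ranges), c_g genotype effects and c_r ~ N(0, sigma_r^2 I) row
  effects; REML by effective-dimension updates; generalized heritability
  H^2 = ED_g / (n_g - 1); BLUEs and spatially corrected plot values.
* **Agreement statistics** -- Bland-Altman and regression between blending
  modes, cross-flight correlation matrices, stay-green subsetting.
* **A synthetic campaign generator** -- an augmented 2-replicate design of
  354 wheat genotypes (378 plots/replicate), a directional soil/canopy
  mixture model calibrated to a ~3.5 degC apparent-temperature span across
  the sensor FOV, a 640 x 512 / 25 x 20 degree camera flown at 80 m and
  2.2 Hz with >=70%/>=90% overlaps, thermal cross GCP targets, NETD noise
  and ambient drift -- so the whole chain can be validated against known
  ground truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from thermofield.pipeline import RunConfig, run_simulation_study

result = run_simulation_study(RunConfig(seed=1))
print(result.heritability.to_string(index=False))
print(f"Bland-Altman bias: {result.agreement.bias:.2f} degC, "
      f"mode regression slope {result.regression[1]:.2f}, "
      f"R2 {result.regression[2]:.2f}")
```

prints (one simulated midday flight, ~750 frames, both blending modes):

```
blending_mode       h2  ed_genotype  n_genotypes  var_genotype  var_residual
      average 0.527156   186.086086          354      0.415346      0.704247
     disabled 0.418475   147.721661          354      0.321684      0.856141
Bland-Altman bias: -1.13 degC, mode regression slope 0.99, R2 0.95
```

Read: the simulated truth has a variance-ratio heritability of 0.6.
Averaging all viewing geometries (`average`) recovers H^2 = 0.53 and a
residual variance of 0.70, while nadir-closest image selection
(`disabled`) leaves more viewing-geometry noise in the plot values
(residual 0.86) and a lower H^2 = 0.42 -- the central practical finding
this pipeline is built to expose.  The negative Bland-Altman bias says
near-nadir imagery reads warmer (it sees more sunlit soil between the crop
rows); the near-unit slope and high R^2 say the two modes still rank plots
almost identically.

The same chain is scriptable stage by stage:

```bash
thermofield --seed 1 --outdir run1 design
thermofield --seed 1 --outdir run1 simulate
thermofield --seed 1 --outdir run1 mosaic --mode both
thermofield --seed 1 --outdir run1 extract
thermofield --seed 1 --outdir run1 fit
thermofield --seed 1 --outdir run1 agree
# or all at once:
thermofield --seed 1 --outdir run1 run-all
```

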