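# lvke — left-ventricular blood kinetic energy from 4D-flow CMR

`lvke` turns time-resolved three-directional phase-contrast MRI ("4D flow")
velocity fields and left-ventricular (LV) segmentations into quantitative
measures of intracardiac blood flow:

* **KE time curves** — the total kinetic energy of LV blood per cardiac
  phase, `KE = Σ_voxels ½ m v²` with `m = ρ · V_voxel` (blood density
  ρ = 1050 kg/m³), reported in mJ;
* **vortex-ring partitioning** — the diastolic vortex ring that forms
  downstream of the mitral valve is bounded by Lagrangian coherent
  structures, computed as ridges of the backward-time finite-time Lyapunov
  exponent (FTLE) field `σ = ln√λmax(∇Φᵀ∇Φ) / |T|`, and LV KE is split into
  inside- and outside-vortex parts;
* **diastolic curve taxonomy** — heart-failure KE time curves fall into
  three morphologies (E-wave peak below the A-wave peak; E above A; fused
  E/A peaks), which the package detects automatically and compares against
  diastolic-dysfunction grades with Cohen's kappa.

It is aimed at cardiovascular imaging researchers who have velocity volumes
and endocardial delineations and want reproducible KE quantification without
a GPU or a vendor workstation. Preprocessing (temporal phase unwrapping
against the VENC limit, stationary-tissue background correction by an affine
fit, resampling to 40 cardiac phases), LV volumetrics (EDV/ESV/SV/EF,
PER/PFR, systole/diastole/diastasis partition), particle tracing (RK4) and a
synthetic beating-LV generator with analytic ground truth are all included.

## Data layout

A flow dataset is a directory with three scalar 4D NIfTI files
(`vx.nii.gz`, `vy.nii.gz`, `vz.nii.gz`, cm/s, components along the physical
axes of the shared affine) and a JSON sidecar:

```json
{"rr_ms": 1000.0, "venc_cm_s": 100.0, "timestamps_ms": [0.0, 25.0, ...],
 "density_kg_m3": 1050.0, "subject_id": "s01"}
```

Masks (LV blood pool, stationary tissue, vortex) are 4D 0/1 NIfTI volumes on
the same grid.

## Worked example

Simulate a heart-failure-like exam (dilated LV, E-dominant filling) and run
the full pipeline:

```sh
lvke run --out out/ --seed 1 --config cfg.json
```

with `cfg.json`:

```json
{"synthetic": {"shape": [32, 32, 32], "spacing": [4, 4, 4],
               "vortex_radius_mm": 10, "pattern": "p2",
               "edv": 348, "esv": 264}}
```

The run writes `ke_curve.csv`, `ke_summary.json`, `labels.csv`,
`vortex.nii.gz`, a provenance log and a KE time-curve plot. The summary for
this exam reads (abridged):

```json
{"sys_avg": 1.013, "dia_avg": 0.346,
 "sys_peak": 3.214, "dia_peak": 1.543,
 "cv": 1.399, "vortex_fraction": 35.66,
 "delta_ke_diastole": 0.630, "delta_vortex_volume": 15.87}
```

Read: systolic-average KE 1.01 mJ and diastolic-average 0.35 mJ over the
cycle; the diastolic KE peak (1.54 mJ) is the E-wave inflow; 35.7 % of
diastolic KE sits inside the automatically extracted vortex ring; and
inside-vortex KE rises by 0.63 mJ from vortex formation to end-diastole
while the ring grows by 15.9 ml. `labels.csv` carries the detected pattern
(`p2`: E-dominant, non-fused peaks) with the E/A peak heights.

The same operations are available as a library:

```python
from lvke import synthetic_data, volumetrics, kinetic_energy

field, lv, stationary, truth = synthetic_data.make_lv_cycle()
vcurve = volumetrics.compute_volume_curve(lv, field.spacing,
                                          field.timestamps, field.rr_ms)
vols = volumetrics.compute_volumetrics(vcurve)     # EDV/ESV/SV/EF, PER/PFR
kef = kinetic_energy.compute_ke_field(field)        # ½ρV|v|² per voxel, J
ke = kinetic_energy.sum_region_ke(kef, lv)          # mJ per phase
```

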