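# Methods

## Model and units

Blood kinetic energy is computed voxel-wise as `KE = ½ m |v|²` with
`m = ρ · V_voxel`, blood density ρ = 1050 kg/m³ by default, and `v` the
velocity vector measured by phase-contrast MRI. Velocities are stored on
disk in cm/s (the native phase-contrast unit) and converted to m/s
internally; KE fields are in joules per voxel, curves and summaries in mJ,
and volume-indexed averages in μJ/ml (average in mJ divided by the indexing
volume in ml, times 1000). Volumes are in ml, spacing in mm, times in ms.
Inside the integrator, velocities in m/s equal mm/ms, so particle positions
in mm and times in ms need no conversion.

"Average KE inside the vortex" is interpreted as the **spatial sum** of voxel
KE over the vortex region per phase, then the temporal average over the
diastolic vortex phases. The alternative per-voxel-mean reading was
rejected: only the spatial-sum reading yields inside/outside components on
the same mJ scale as the total LV curve, and makes inside + outside equal
the total exactly (which the implementation guarantees bit-exactly by
summing complementary index sets in a fixed order).

The diastolic ΔKE ("maximum change from vortex formation to end-diastole")
is directional in ordinary language but of unstated sign; it is implemented
as the **signed change of maximal absolute value** relative to the formation
phase, earliest sample winning ties. The same rule is used for Δvortex
volume and over diastasis.

The curve coefficient of variation uses the sample (n−1) standard deviation
of the full 40-phase total-KE curve divided by its mean.

## Preprocessing chain

The fixed order is unwrap → fit background → correct → resample.

* **Unwrapping** is temporal: each voxel's per-component time series is
  unwrapped along the phase axis with period 2·VENC (`numpy.unwrap`), then
  reconstructed exactly as `original + k · 2·VENC` with integer `k`. A wrap
  present at *every* phase produces no temporal jump and is invisible to
  this pass — a documented limitation shared by any purely temporal method.
  Equally, a true inter-phase velocity jump larger than VENC will be
  "corrected"; the method presumes the underlying signal is temporally
  smooth relative to VENC.
* **Background correction** models each phase and velocity component as an
  affine function of physical position, `v ≈ a + b·x + c·y + d·z` (offset
  cm/s, slopes cm/s/mm), least-squares fitted over stationary-tissue voxels
  with coordinates centered on their centroid for conditioning, and
  subtracted everywhere. At least 16 stationary voxels per phase are
  required and a rank check rejects coplanar/collinear stationary sets.
  First order in space is deliberate: higher-order eddy-current models are
  out of scope.
* **Resampling** to `n_target` (default 40) uniform phases is periodic
  linear interpolation in time, voxel-wise per component.

## Volumetrics and the phase partition

ED is the global volume maximum and ES the global minimum (ties to the
earliest phase); phase index sets are enumerated cyclically starting at ED,
so systole = [ED, ES) and diastole = [ES, ED). dV/dt uses cyclic central
differences without smoothing. PER/PFR are the extrema of ∓dV/dt over
systole/diastole.

E/A timing is derived from dV/dt of the volume curve, not from transmitral
flow: the E-wave runs from ES to the first phase after the peak filling rate
where dV/dt falls below α·PFR (α = 0.2 by default), the A-wave starts where
dV/dt last rises above that threshold before the final diastolic filling
peak, and diastasis is the remainder (possibly empty). With a single
filling peak the whole diastole is E-wave. This dV/dt surrogate is a design
choice of this package; clinical E/A definitions use the transmitral inflow
jet itself.

## FTLE / vortex extraction

Particles are advected by classic fixed-step RK4 through a field that is
trilinear in space and linear-periodic in time; the default step is half the
inter-phase spacing, adjusted to divide the span exactly. Particles whose
RK4 stages leave the spatial domain are frozen at their last position and
flagged; FTLE values whose central-difference stencil touched a frozen
particle, or that lie on the seed-grid boundary layer, are NaN.

The flow-map gradient is taken by central differences over neighbouring
seeds of a structured seed grid (voxel centers of the LV bounding box);
along degenerate grid axes (size < 3) the gradient column is the identity,
which handles quasi-2D benchmark grids. σ = ln√λmax(C)/|T| with
C = (∇Φ)ᵀ(∇Φ) and T in seconds.

The vortex ring is bounded by **backward-time** FTLE ridges on diastolic
phases (attracting structures bound an inflow vortex); forward is available
by flag. The integration span is the elapsed diastole at the seeded phase,
capped at half the cycle. Ridges are voxels above the q-th percentile
(q = 90) of σ within the LV; the ridge set is morphologically closed with a
radius-1 Chebyshev (26-connected) element — a 6-connected element leaves
diagonal gaps in thin ridge shells — hole-filled, intersected with the LV,
and the connected component containing the centroid of the basal third of
the LV (the mitral-inflow side) is kept. The extraction is deterministic
given (σ, LV, parameters). User-supplied vortex masks bypass the heuristic
entirely. In the clinical workflow this delineation was manual; the
automated heuristic is validated only against synthetic ground truth, where
the extracted volume of a translating Hill vortex inside an LV-sized
chamber is recovered within ±25 %.

A note on frames: the FTLE of the steady co-moving Hill vortex equals that
of the unsteady lab-frame translating vortex (Galilean invariance), but only
the lab frame keeps exterior particles inside a finite grid, so the
synthetic validation uses the translating lab-frame field.

## Curve-pattern classification

Candidate diastolic peaks are local maxima with prominence ≥ p·(diastolic
maximum), p = 0.10, located on a cyclic 3-point moving average of the curve
so isolated noise samples do not masquerade as peaks; reported peak
amplitudes are read from the raw curve at the detected positions. E is the
earliest candidate and A the latest. Fusion (pattern 3) is fewer than two
candidates or an inter-peak trough above θ·min(E, A), θ = 0.7. Spill-over
flags KE at systole onset above s·(diastolic maximum), s = 0.5. Non-fused
curves are pattern 1 if E < A and pattern 2 (patients) or control-like
(controls) if E > A; an exact tie maps to pattern 2 with a tie flag. The
published classification was by visual consensus; (p, θ, s) are this
package's operationalisation, configurable and reported alongside labels.

Cohen's kappa is unweighted, `κ = (Po − Pe)/(1 − Pe)`, with the large-sample
standard error `√(Po(1−Po)/(n(1−Pe)²))` and a normal-theory 95 % CI.
Subjects with undetermined dysfunction grade are excluded from the table;
categories align pattern 1 ↔ impaired relaxation, 2 ↔ pseudonormal,
3 ↔ restrictive.

## Synthetic data: what it emulates and what it does not

`make_lv_cycle` generates an axis-aligned ellipsoidal LV (long axis 1.6×
the short axes) whose volume follows a prescribed curve — systolic emptying
to ESV, then E- and A-wave refilling shaped by the requested pattern with
per-pattern E/A inflow-velocity ratios (control-like 2.0, pattern 1 0.6,
pattern 2 1.6, pattern 3 fused) — a diastolic inflow jet whose amplitude
tracks the instantaneous filling rate, a translating Hill-type vortex during
filling, a systolic outflow jet, and a stationary shell around the LV.
Geometric realism is deliberately sacrificed for exact volume control: the
mask takes exactly `round(V(t)/V_voxel)` voxels in order of ellipsoidal
radius, so mask volumes match the prescription within one voxel per phase.
Intraventricular velocities are tapered smoothly to zero at the moving wall
(a no-slip-like envelope), so mask motion never creates artificial
inter-phase velocity jumps.

Corruptions are opt-in and applied in the order background → noise → wrap:
an affine background added over the whole grid (the stationary shell then
carries exactly that field), additive Gaussian per-component noise (SD in
cm/s), and aliasing by the wrap model `((v + VENC) mod 2·VENC) − VENC`.
Defaults describe an idealised healthy exam (48³ voxels at 3 mm, 40 phases,
RR 1000 ms, VENC 100 cm/s, EDV 150 ml / ESV 60 ml, no corruption); tests
exercising recovery switch the corruptions on explicitly.

What passing tests on this generator show: unit/bookkeeping correctness,
exact conservation, analytic-oracle agreement (Hill energy, saddle FTLE,
RK4 order), and parameter recovery under controlled corruption. What they
do not show: behaviour on real trabeculated anatomy, valve geometry,
turbulence, through-plane motion of the basal plane, or spatially
correlated MRI noise — none of which the generator models.

### Analytic oracles

The Hill-vortex interior energy in the co-moving frame is
`KE = (3π/7) ρ U² a³`, derived symbolically from the interior stream
function and frozen as `hill_vortex_ke`. The voxel-sum KE converges to it
under grid refinement; because the center-in-sphere boundary term is
lattice-sensitive, single-halving error ratios fluctuate, so the per-halving
ratio is measured across two halvings (√ of the error ratio between spacings
h and h/4), giving a stable ≥3× contraction. The double-gyre benchmark is
the standard time-periodic stream-function flow on [0,2]×[0,1], extruded in
z, with the cycle period as its period; its FTLE is checked by self-
convergence against a refined-step computation.

## Problem sizes and defaults

Tests and the acceptance script run the full exam at 32³ voxels of 4 mm
(40 phases) and the vortex-extraction scenario at 40³ of 3 mm — sizes chosen
so the whole suite completes in well under a minute while keeping >10 voxels
across every structure of interest; the generator's default remains the
acquisition-typical 48³ at 3 mm. The classifier recovery property uses 200
seeded replicates per pattern at 10 % noise. All random number streams are
`numpy.random.default_rng` seeded explicitly; generators are bit-reproducible
under a fixed seed.

## Known limitations

* Temporal unwrapping cannot recover constant (all-phase) aliasing, and
  misinterprets true inter-phase jumps larger than VENC.
* The FTLE-ridge vortex heuristic was validated on synthetic translating
  vortices only; against manual clinical delineations its agreement is
  unknown.
* The E/A partition from dV/dt can differ from transmitral-flow timing in
  subjects with discordant wall motion.
* Cohort-level group statistics (rank tests, regressions) are out of scope;
  the package produces the per-subject measures those statistics consume.
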