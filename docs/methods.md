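# Methods

`synctplan` evaluates whether a synthetic CT (synCT) derived from Dixon MR
tissue classification supports dosimetrically faithful photon treatment
planning for lung targets, where tissue inhomogeneity makes dose the most
sensitive to CT-number errors.  Because no patient data ships with the
package, every experiment runs on parametric digital thorax phantoms whose
statistical structure mimics the clinical inputs.  This note documents the
models, the defaults and their rationale, the numerical choices, and what
the phantom experiments can and cannot say about real data.

## Digital thorax phantom

The phantom is a set of analytic shapes rasterized at voxel centers
(`origin + (index + 0.5) * spacing`): an elliptic-cylinder body (semi-axes
110 x 85 mm) with a subcutaneous fat shell (outer 10% of the body radius),
two lung ellipsoids (semi-axes 44 x 58 x 97 mm), a spherical heart, a
vertebral column (16 mm radius) enclosing a spinal cord (5 mm), all inside a
240 mm field of view (default 96^3 voxels at 2.5 mm isotropic).  Later
organs carve earlier ones (heart and spine displace lung), so label map and
structure masks are mutually consistent by construction.

Ground-truth CT numbers are piecewise constant at the class anchors -1000
(air), -110 (fat), -767 (lung) and 70 HU (soft tissue), plus Gaussian voxel
noise (default SD 20 HU, a typical thorax-CT noise level; the source study
reports no patient noise model, so this is a free parameter).  Vertebral
bone carries a cortical-rim-to-marrow-core gradient: linear in attenuation
coefficient from 0.2485 cm^-1 at the rim to 0.1 cm^-1 at the deepest core
(normalized Euclidean distance transform), mapped through the same
bilinear LAC-to-HU conversion used for the synCT.  Making the phantom's
truth consistent with the atlas bone model is deliberate: it is what lets a
perfect pipeline reproduce the planning CT exactly, so end-to-end
disagreement measures pipeline error, not an arbitrary modelling mismatch.
A uniform-HU spine (336 HU, a typical patient-cohort mean) remains
available as an option.

The PTV is a sphere of lung voxels: a center is chosen inside a lung
(feasibility via the lung mask's distance transform), and exactly
`round(volume / voxel_volume)` nearest voxels are taken, so the mask volume
is within half a voxel of the drawn target.  Size classes draw volumes from
Normal(11.9, 5.5), Normal(83.5, 14.5) and Normal(222.3, 39.8) cm^3,
truncated at +-1.5 SD — inside the modelled +-2 SD band, and necessary for
the largest draws to remain placeable inside a phantom lung.  Location
classes (apex, mediastinum, ribs, spine) pull the center toward the
corresponding lung landmark subject to feasibility; very large targets
necessarily gravitate toward the lung center, as they would anatomically.
PTV voxels keep the lung label: as in the clinical workflow, the
water-equivalent tumor density (-4 HU) is imposed at planning time on both
CTs, never in the anatomy.

The Dixon simulation assigns per-class (water, fat) signal means — air
(0, 0), lung (12, 4), soft tissue (100, 12), fat (15, 110), arbitrary
units — on the (typically coarser) MR grid, default 2.60 x 2.60 x 3.12 mm,
plus optional Gaussian noise.  Bone voxels receive the soft-tissue
signature: marrow and cortex are not separable in Dixon contrast, which is
precisely why the atlas stage exists.  The table is chosen so that the
declared classifier recovers the 4-class projection of the labels exactly
at zero noise (a round-trip identity the tests enforce).

Breath-hold-vs-free-breathing misalignment is a smooth random displacement
field: white noise on a 4^3 control grid, cubic-spline upsampled, scaled so
the maximum voxel norm equals the requested magnitude.  The warped volume
samples the input at `x + u(x)`, and `u` is returned as ground truth for
registration-recovery tests.

What the phantom does **not** emulate: MR bias fields and chemical shift,
ribs and scapulae, bronchial trees, cardiac and respiratory motion,
truncation artifacts, and continuous HU heterogeneity within organs.
Passing tests therefore demonstrate internal consistency and sensitivity of
the dosimetric chain at clinically plausible error scales — not clinical
performance on patients.

## Classification and attenuation map

The classifier is rule-based and deterministic: body = largest connected
component of above-threshold combined signal with holes filled (the filled
holes are exactly the enclosed lungs); inside the body, low-signal
components above 50 cm^3 are lungs (smaller pockets stay air); the rest
splits by fat fraction F/(W+F) at 0.5, ties to fat.  Both intensity
thresholds are fractions (0.3) of the 99th percentile of the combined
signal, so classification is invariant to global rescaling of both
channels; no absolute thresholds are used.  Class LACs at 511 keV are the
published map: air 0.0, fat 0.0854, lung 0.0224, soft tissue 0.1 cm^-1.

## Bone atlas

The desk-scale atlas is built from the canonical noiseless phantom: its
water image, its vertebral mask with the rim-to-core LAC gradient, and
eight geometric landmarks (lung centers and apexes, heart center, cord
ends, sternum).  Registration is two-stage: closed-form least-squares
affine on shared landmarks (>= 4, non-coplanar), then an optional
intensity-based deformable refinement.  Insertion warps each bone mask into
patient space and overwrites fat and soft-tissue voxels only — bone never
replaces air or lung, keeping the map anatomically possible — with values
clamped to [0.1, 0.2485] cm^-1; the operation is idempotent.

For gradient-model bones the LAC pattern is *recomputed* on the warped mask
rather than interpolated from atlas values: value interpolation smooths the
thin cortical rim and systematically lowers inserted bone attenuation
(measured as a ~0.3–0.5 percentage-point bias in end-to-end PTV D95 before
the change).  Incidentally, bone is also where the clinical study found its
only significant mean-HU disagreement, in the same direction.

## Synthetic CT

LAC-to-HU conversion is the monotone piecewise-linear map through the five
printed anchors (0, -1000), (0.0224, -767), (0.0854, -110), (0.1, 70),
(0.2485, 2661); the published class values are honored exactly and bone is
linear between marrow and cortical endpoints.  The parameters of the
"standard bilinear" kVp conversion are not published, so exact anchor
interpolation is the design choice.  Resampling uses trilinear
interpolation for continuous volumes and nearest-neighbour for labels and
masks (value set preserved); the clinical planning spacing of
1.25 x 1.25 x 2.5 mm is the config default for the resampler, while the
study fixture computes on 2.5 mm isotropic 96^3 grids (240 mm coverage;
2.5 x 2.5 mm in-plane equals the dose-calculation grid).

synCT-to-planCT alignment is 6-DOF rigid (mean-squares metric,
multi-resolution) followed by deformable refinement.  The default
deformable stage is a free-form deformation on a coarse B-spline control
grid (60 mm knot spacing, LBFGS-B, regular 25% metric sampling with fixed
seed): for smooth breathing-scale fields, the control-grid parametrization
interpolates displacement through flat image regions where intensity gives
no signal, which is exactly where demons forces vanish.  A multi-resolution
symmetric-forces demons stage is available as an alternative.  Both stages
verify their similarity metric improved and raise otherwise.

## Dose engine

The engine is a deliberately simple, closed-form-testable stand-in for a
commercial convolution/superposition algorithm, keeping the two physical
effects that make lung dosimetry sensitive to CT errors — photon
attenuation along the water-equivalent path, and density-dependent lateral
spread:

    D = w * ISF * exp(-mu_eff * d_rad) * P(u, v; sigma_eff)

* `d_rad` is the cumulative density-weighted depth from the beam entry,
  computed in a beam-aligned frame (the volume is resampled so the beam
  axis is a grid axis and depth is a cumulative sum).  The standalone
  `radiological_depth` operation is exact Siddon-style voxel-intersection
  ray tracing, verified against a 0.01 mm step numerical integral.
* `mu_eff` defaults to 0.005 mm^-1, a 6-MV-like effective attenuation.
* `P` is a flat field convolved with a Gaussian penumbra; its width
  `sigma_eff = sigma_lat / max(rho, rho_floor)` (defaults 3 mm, floor 0.15)
  broadens in low-density lung, the lateral-transport analogue.
* `ISF` is the inverse-square factor in divergent mode (source-axis
  distance 1000 mm; lateral coordinates projected to the isocenter plane;
  the depth integral remains along parallel rays, an approximation valid
  while the field of view is small against the SAD).  Parallel mode, used
  by the closed-form tests, sets ISF = 1.

Monitor units are modelled as per-beam scalar weights; fluence modulation
is out of scope.  Weights are fitted by non-negative least squares over
sampled PTV voxels (target = prescription) and organ-at-risk voxels
(penalty 0.3 toward their bounds; cord 45 Gy and heart 40 Gy defaults —
the source study's "conventional objectives" are not enumerated, so these
are this package's defaults, not its claims).  If the initial weights
already achieve an equal or lower objective they are kept; infeasible bound
sets yield a best-effort solution with a warning.  Normalization multiplies
weights and dose by `prescription / D95(PTV)` so 95% of the PTV receives
the full prescription; recomputation on the other CT reuses the identical
beams and weights ("same MUs") and only swaps the density grid.  The
HU-to-density calibration curve is piecewise linear through (-1000, 0),
(0, 1.0), (70, 1.04), (1000, 1.52), (3071, 2.59) — a representative
clinical shape, since the study's scanner curve is unpublished.

For speed, a finite lateral beam-frame margin (field edge + 50 mm in the
pipeline) truncates the penumbra tail; the default (`None`) covers the
whole grid exactly and is what the closed-form tests use.

## DVH conventions

Dx is the largest dose d with at least x% of the structure at or above d,
computed by exact order statistics (the ceil(n*x/100)-th largest voxel
dose); 100 voxels dosed 1..100 Gy give D95 = 6 Gy.  Vx counts voxels with
dose *strictly* greater than x Gy ("receiving dose larger than x Gy" read
literally; the same 1..100 case gives V20 = 80%, not 81%).  PTV Dx is
reported as % of prescription (the alternative, % of maximum dose, is not
used; the choice is flagged here because the convention is not stated in
the source).  Lung is evaluated as both lungs minus the PTV; heart by V40;
cord by maximum voxel dose.  The cumulative DVH uses 0.01 Gy bins; curve
plateaus resolve Dx to the larger dose (deterministic tie-break), and the
binned curve agrees with the exact order statistics within one bin.

## Gamma analysis

Global 3D gamma with criteria 1%/1mm, 2%/2mm, 3%/3mm and a 10% low-dose
threshold applied on the reference dose; voxels below threshold are
excluded from both the gamma map statistics and the pass-rate denominator
(the source does not state the denominator convention; exclusion is
documented here).  Normalization is the global maximum of the reference
dose (the usual "global" convention; prescription normalization is an
option).  The planning-CT dose is the reference and the synCT dose is
evaluated — gamma is asymmetric and the synCT plan is the one on trial.

The minimum is searched over a displacement lattice of step dta/10 within
a radius of 4*dta, with trilinear interpolation of the evaluated dose.
`gamma_map` first bounds each voxel with a coarse pass (step 3*dta/10,
within the dta/3 sub-voxel requirement) and then finishes the dense
lattice exactly: displacements are visited in ascending norm and a voxel
retires when its current minimum is at most (d/dta)^2 for the smallest
remaining norm d — a pruning rule that cannot change the result.
`brute_force_gamma` searches the same dense lattice without the bounding
pass and is the independent oracle; the two agree to the last bit on the
test grids, and the pipeline's coarse-only mode (used inside the 43-plan
study loop for speed) yields upper-bound gamma values, i.e. conservative
pass rates.

A note on the shifted-ramp benchmark: for a 1%-per-mm ramp shifted 1 mm
under 2%/2mm, restricting gamma to whole-voxel displacements gives 0.5,
but the sub-voxel minimum is min_u sqrt(u^2 + (1-u)^2)/2 = 1/(2*sqrt(2))
~ 0.354 at u = 0.5 mm; the brute-force oracle confirms the latter and the
tests assert it.

## Statistics

Paired t-tests on per-plan metric differences (synCT minus planCT), mean
differences with t-quantile 95% confidence intervals (the source does not
say whether t or normal quantiles were used; t is chosen), and two-sided
rank-sum (Mann-Whitney) tests between tumor size and location groups —
read as between-group comparisons of the differences, not signed-rank
tests, since the groups are independent.  Exact p-values for groups up to
12 without ties, normal approximation with tie correction otherwise; the
exact branch is validated against full permutation enumeration.  No
multiple-testing correction is applied, and the report footer says so.

## The study fixture

The standard fixture plans 43 PTVs (18 small, 13 medium, 12 large; 9 apex,
16 mediastinum, 9 ribs, 9 spine, shuffled pairing) across 11 patient
phantoms that are per-axis scaled (+-6%) and shifted (+-4 mm) affine
variants of the canonical thorax — which also means the landmark-affine
atlas stage aligns the spine essentially exactly, so the deformable
refinement is skipped inside the study loop (it is exercised by its own
recovery tests).  Perturbations at the scale of the clinical study: a
per-patient lung HU offset drawn uniformly in +-30 HU (patient lung means
scatter on both sides of the synCT value), CT voxel noise of 20 HU on the
planning CT only (the synCT is piecewise constant by construction, as in
the real method), and a 2 mm smooth residual misalignment applied to the
planning CT — modelling the residue *after* registration, which is why the
registration operators are not rerun inside the loop.  Small PTVs receive
the stereotactic prescription (60 Gy in 3 fractions), medium and large the
conventional one (59.40 Gy in 33 fractions); PTV metrics are expressed in
% of prescription and are comparable across schemes.  Problem sizes
(96^3 grids, 7 beams per plan, coarse-only gamma in the loop) are chosen so
the full study completes in a few minutes on one CPU.

With all perturbations off and matched grids, the synCT equals the
planning CT to floating-point precision and every gamma criterion passes
at 100% — the pipeline's null experiment.  Under the perturbed fixture the
run reproduces the *shape* of the clinical findings (mean 2%/2mm pass rate
above 99%, mean PTV D95 difference within half a percentage point, pass
rates ordered 1%/1mm < 2%/2mm < 3%/3mm); these are phantom analogues
computed by the tests and the pipeline itself, echoing, not reproducing,
the patient results.

## Known limitations

* The dose engine has no scatter kernel, no electron-transport buildup,
  no MLC/collimator model and no absolute-dose calibration; conclusions
  are about CT-number sensitivity, not absolute dosimetry.
* The atlas contains the vertebral column only (the thorax phantom has no
  ribs, matching the source method's atlas, which also excluded ribs).
* IMRT modulation is reduced to per-beam scalar weights; plan quality
  metrics (conformity, OAR sparing) are consequently cruder than clinical
  plans, which is acceptable because both CTs see the same plan.
* Classification is rule-based; its noise robustness is characterized on
  phantom noise only.
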