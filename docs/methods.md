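# Methods

This note documents the models, discretisations, generator designs and
numerical conventions behind `aneukit`, and what the synthetic-data tests do
and do not establish about real data.

## Surface discretisation and WSS metrics

Aneurysm walls are triangle meshes with SI coordinates (m); WSS vectors τ
(Pa) live on vertices, sampled at `n_t ≥ 16` uniform instants over one
cardiac period T. Time integrals use the periodic trapezoidal rule; because
sampling is uniform and the wrap-around sample is identified with sample 0,
every ∮·dt reduces to a plain mean over the stored samples times T.

**Spatial operators.** Per-triangle linear (P1) shape functions give a
constant gradient per face, `∇φ_i = n × e_i / 2A`; vector fields are first
expressed in the face plane, so the face divergence is `Σ τ_i·∇φ_i`. Face
values are averaged onto vertices with area weights (one-sided at boundary
vertices — the neck rim uses whatever faces exist). These operators are
exact for fields linear over a planar patch and first-order accurate on
curved surfaces; on a unit icosphere with edge ≈ 0.033 the maximum error
against the spherical-harmonic closed forms is ≈ 0.3 %. The error scales
with the field's natural gradient magnitude (|τ|/R for curvature-driven
variation), which matters when interpreting WSSD below.

**Metric conventions.**

* OSI and GON are set to 0 where their denominators fall below 1e-12 (zero
  flow); values are clipped to their theoretical ranges [0, ½] and [0, 1]
  to absorb round-off.
* WSSD and WSSG are reported as cycle *averages* (1/T ∮·dt) so units are
  Pa/m for any period; `cycle_average=False` gives the raw integral. GON is
  scale-free under either convention.
* The WSS-gradient vector G defaults to the two-component form
  (∂τ_p/∂p, ∂τ_q/∂q) in the tangent frame (p, q) of the cycle-averaged WSS
  direction — the construction the gradient-oscillatory-number literature
  uses, and the one that makes WSSG and GON share one object. A full
  tangential-Jacobian Frobenius norm is available via
  `gradient_def="frobenius"`. Vertices with vanishing mean WSS get a fixed
  arbitrary tangent frame and are flagged.
* Area indices count whole faces whose three-vertex mean passes the
  threshold *strictly*; summaries (max/min/space-average) run over dome
  vertices with barycentric (one-third) lumped vertex areas, which are
  exactly conservative (Σ vertex areas = Σ face areas).

## Morphology

The neck plane is a required input (point, unit normal toward the dome, and
the ordered boundary loop); automatic neck detection is out of scope. Sac
volume closes the dome with a planar fan cap at the loop centroid and
applies the divergence theorem; orientation is repaired by taking the
magnitude. NSI uses the cap-excluded dome area, so a hemisphere scores
exactly 0 (the constant (18π)^⅓ (2π/3)^⅔ equals 2π). Width W takes the
maximum in-plane Feret diameter over 100 plane-parallel slices (config-
urable); D_neck is the Feret diameter of the projected neck loop, with an
equivalent-area-circle option. All indices are rigid-motion invariant and
scale as s, s², s³ as appropriate; AR = HWR × BF holds identically.

## 0D models

The three-element Windkessel is integrated with explicit Euler (the update
used when such outlet models are coupled to a 3D solver), dQ/dt by centred
periodic differences on the resampled dt grid, default dt = 1 ms. The
integrator runs until consecutive cycles agree to 0.1 % of pulse pressure;
divergence raises an error naming the stability limit dt < 2 R_d C. At
dt = 1 ms the trajectory is within 0.5 % of an adaptive high-order
reference, and the sinusoidal response matches the analytic transfer
function R_p + R_d/(1 + iωR_dC) to 0.1 % amplitude. Initial pressure
defaults to R_T × mean(Q). Outlet resistance assignment realises a target
steady flow division against a common reference pressure (R_T,i = P/(f_i Q))
with R_p/R_T = 0.2 and a distal time constant R_d·C of 1.0 s by default (a
typical systemic decay time); compliance follows from that choice.

Blood properties default to ρ = 1060 kg/m³ and Carreau constants
μ0 = 0.056 Pa·s, μ∞ = 0.00345 Pa·s, λ = 3.313 s, n = 0.3568.

## Synthetic-data generators

The generators stand in for patient CTA geometry and solver WSS output,
which are not publicly available. They emulate *structure*, not hemodynamic
realism: a passing test shows the pipeline recovers known planted signals
at documented tolerances, not that real aneurysms behave this way.

**Domes.** Spherical caps (default radius 2 mm, hemispherical opening)
meshed by latitude rings with per-ring azimuthal counts (even counts so the
rim's Feret diameter is exact), with optional real-spherical-harmonic
radial bumps (amplitude < 0.3 R for meshability) tapered to zero at the rim
so the neck stays planar. Deterministic under seed (the seed jitters ring
phase offsets).

**Pulsatile fields.** A two-harmonic pulse shape s(t) = 1 + 0.6cos + 0.2cos2
(mean 1, systolic peak 1.8, strictly positive) modulates an azimuthal base
swirl of 5 Pa. Planted features and their recovery contracts, at mesh edge
lengths ≲ 0.1 mm on a 2 mm dome:

| feature | construction | contract |
|---|---|---|
| high_wss_spot | magnitude blended to the target at the centre | TAWSS within 10 % |
| converging_sink | inward field −(A/2)·d·ê_d (divergence −A), tapered | WSSD within 15 % |
| oscillation_patch | base blended out, reversing cos(2πt/T) term in | OSI ≥ 0.4 (→ ½ at full reversal) |
| high_gradient_rim | field turned radial with magnitude ramp of slope g | WSSG within 20 % on the rim |

The base swirl is suppressed to exactly zero inside the sink core: the
discrete divergence error of a 5 Pa field on a 2 mm dome is of order
|τ|/R ≈ 2.5 kPa/m times the operator error, which would otherwise swamp a
planted divergence of −12 Pa/m at any practical resolution. This mirrors a
genuine property of real WSS fields — their divergence (±15 Pa/m) is tiny
relative to their gradient scale (≈ 10⁴ Pa/m), i.e. they are nearly
divergence-free — but it means the sink contract validates the operator on
the planted field, not on the superposition with an arbitrary background.

**Cohorts.** Two groups (default 20/20) with per-parameter means/SDs
defaulting to the published 40-aneurysm comparison table. Marginals are
moment-matched lognormals for strictly positive scale parameters, normals
for bounded indices, and a negated lognormal for minWSSD (with the latent
normal's sign flipped so rank correlations keep their requested sign).
Dependence is a Gaussian copula: requested Spearman ρ_s is converted to the
latent Pearson ρ = 2 sin(πρ_s/6), the matrix repaired to PSD by eigenvalue
clipping, applied to the parameters the published correlation matrix
covers. The published table's length units are implausible as metres
(a 4.4 cm sac height); the generator therefore treats those numbers as
given dimensionless defaults rather than silently rescaling them. Mesh- and
field-level code is strictly SI.

**Parameter-recovery cohorts.** For the logistic recovery experiment the
starred polynomial predictor is drawn from a four-cluster lognormal mixture
(clusters 0.25/0.9/3.0/6.5, weights 0.61/0.24/0.095/0.055, within-cluster
CV 8 %) spanning the regions where the quadratic logit is informative: at
n = 4000 the resulting Fisher information puts every coefficient's relative
standard error near 3–5 %. Each predictor is divided by its sample mean —
starred predictors are cohort-mean-normalised by definition, so refitting
re-normalises by exactly 1. NSI* and AR* are lognormal with CV 0.25/0.5.

**Threshold-sweep cohorts.** Per-aneurysm WSSG-like scalar maps on a shared
dome. Every aneurysm gets a label-independent focal patch peaking just
above the separating band's floor (1.0–1.15×, radius 0.5–0.9 rad), so
thresholds *below* the band expose patch-core areas on every dome with
label-independent sizes, mixing group ranks; ruptured aneurysms also get a
smaller patch peaking above the band's ceiling (1.15–1.4×, radius 0.25–0.35
rad), so any threshold *inside* the band exposes a patch-sized area only on
ruptured domes. The null mode is a pure magnitude-scale family: one shared
spatial pattern times a lognormal per-aneurysm scale (CV 0.3), the cleanest
"identical groups" null in which every threshold induces the same area
ranking.

## Statistics

* Mann-Whitney U: exact enumeration for pooled n ≤ 20 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction; a pooled-constant sample returns p = 1. Measured type-I error
  at n = 20/20, α = 0.05: ≈ 0.049.
* Threshold sweep: 200 uniform candidates between the pooled 1st and 99th
  percentiles by default; optimal threshold = arg-min of the area p-curve
  (ties toward the smaller threshold), no multiplicity correction — this
  mirrors the published procedure; a Bonferroni-across-grid option exists
  but is off by default. **Type-I inflation, measured, not hidden:** the
  uncorrected min-p sweep is a maximally-selected rank statistic. At tail
  thresholds the area index dichotomises the cohort (only the top-k
  aneurysms have nonzero area), and scanning k is itself multiple testing —
  a top-4 single-group split alone yields a tie-corrected p ≈ 0.04. Under
  the scale-family null about 20–30 % of 20/20 cohorts show some grid point
  with p < 0.05 (richer nulls inflate further), even though the planted-
  band experiments recover the true band essentially always. Significance
  claims from such sweeps should therefore rest on the valley's breadth and
  depth, not on any single sub-0.05 grid point. The acceptance suite
  asserts the idealised ≤ 5 % bound as specified and the corresponding test
  is expected to fail by roughly this margin; the measured rate is reported
  by `scripts/acceptance.py`.
* ROC: AUC by average ranks (= pairwise concordance with ties ½);
  operating point maximises Youden's J over midpoints between distinct
  scores, ties resolved toward higher sensitivity.
* Logistic models: unpenalised maximum likelihood (Newton) on starred
  predictors expanded to per-predictor polynomial orders; events-per-
  variable < 5 warns; complete separation raises instead of returning
  diverging coefficients. Single-predictor order selection maximises
  in-sample (apparent) AUC, ties toward the lower order — apparent AUC is
  what small-cohort studies report, and no resampling correction is
  applied.

## Pipeline

`run_pipeline` executes cohort → fields → sweep → fit → report with
per-stage seeds spawned from one master seed; every CSV carries the
configuration hash (output path excluded) and master seed in a header
comment, and identical configurations reproduce outputs bit for bit. The
demo stages use a ~2 mm dome at 0.2–0.3 mm edge length and a 20/20 cohort
so a full run takes seconds.

## Known limitations

* The P1 operators are first-order on curved surfaces; point values of
  WSSD on coarse, irregular meshes inherit errors proportional to the
  field's natural gradient scale.
* The (p, q) gradient-vector definition and the cycle-average convention
  are choices among defensible readings of the standard definitions; the
  alternatives (Frobenius norm, raw integrals) are implemented behind
  flags and give nearly indistinguishable cohort-level conclusions for
  T ≈ 1 s.
* Synthetic cohorts match first/second moments and rank correlations, not
  the joint physics of real aneurysms; morphology and hemodynamics are
  generated independently unless the copula links them.
* No volumetric meshing, CFD, CTA segmentation, or automatic neck
  detection.
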