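# Methods

## The measurement model

The package computes retinal oxygen extraction for one measurement
session from three inputs: per-vessel paired readings (oxygen
saturation, vessel diameter and distance to the optic nerve head from
retinal oximetry; mean blur rate `Q` from laser speckle flowgraphy at
the same vessel segment), per-subject physiology (hemoglobin, capillary
blood gases), and the LSFG summaries of the optic nerve head
(large-vessel index `MV`, tissue `MT`, whole-area `MA`).

The chain, in order:

1. **Wall-loss correction.** Between the fundus measurement point and
   the central vessels, oxygen diffuses through the vascular wall. The
   saturation drop over a segment of radius `R` and length `L` carrying
   flow `Q` is `ΔS = −2πRLJ̄O₂ / (1.35 · Q · Hb)`, with `J̄O₂` the
   (signed) trans-wall flux. `ΔS` is added to arterial and subtracted
   from venous measured saturations. No flux value is published for
   this setting and `Q` is in arbitrary speckle units, so the absolute
   flux scale is a unit convention; the default is `J̄O₂ = 0`
   (correction disabled, the corrected chain reduces exactly to the
   measured saturations). An illustrative non-zero value
   (`EXAMPLE_WALL_FLUX = −7e−6`, ≈0.5 percentage points for a typical
   artery) ships for users who want the correction, as an explicit
   opt-in rather than a silently invented constant.
2. **Central merges.** `SaO₂,CRA` = unweighted mean of corrected
   arterial saturations; `SaO₂,CRV` = flow-weighted mean of corrected
   venous saturations (weights `Q_j/ΣQ`). Both are symmetric in vessel
   order; the venous merge requires strictly positive total venous flow
   (validated up front).
3. **Contents.** `cO₂ = 1.35·Hb·S + 0.003·PO₂` in mL O₂/dL.
   Venous `PO₂` comes from inverting the Severinghaus dissociation
   curve `S(P) = (23400·(P³+150P)⁻¹ + 1)⁻¹` at `SaO₂,CRV` (bracketed
   root finding on [0.1, 700] mmHg, tolerance 1e−10 mmHg — tight enough
   that the dissolved term is exact to ~1e−13 of a content unit).
4. **Extraction.** `extO₂ = (cO₂,CRA − cO₂,CRV)·MV`, in arbitrary
   units because `MV` is. Every analysis downstream uses percent
   changes or ratios only; the pipeline is exactly invariant under a
   common rescaling of all flow indices.

### Where arterial PO₂ comes from

The content formula needs `PO₂,CRA`. Two sources are plausible: the
subject's measured systemic capillary pO₂, or the dissociation curve
inverted at the corrected arterial saturation. The package default is
**from the saturation**, for an internal-consistency reason: under
100% oxygen breathing, capillary pO₂ is ≈340 mmHg, and putting that
into the dissolved term makes the arteriovenous content difference
almost insensitive to the gas challenge (the dissolved gain cancels the
saturation-gap narrowing), which contradicts the well-replicated
finding that the content difference and extraction fall substantially
under hyperoxia when computed from these devices. Deriving both pO₂
values from the same dissociation curve keeps the dissolved term on the
same physiological scale as the bound term (a few percent of it) at
every gas state. The systemic source and a user constant remain
available via `RunConfig.po2_cra_source`; the choice only perturbs
results through the small `0.003·PO₂` term at normoxia.

## Statistical surface

* **Contrasts.** Per study day and variable, the subject's same-day
  baseline (default: mean of the two room-air baselines; first/second
  selectable) is compared with the gas session by a two-sided paired
  t-test; cohort summaries are the mean ± SD of per-subject percent
  changes. The two study days are compared by a paired
  difference-of-differences (day-by-time interaction) test on subjects
  measured on both days — a deliberately transparent formulation of a
  repeated-measures comparison that needs no model-fitting machinery
  and is exactly reproducible. Shapiro–Wilk normality is reported as a
  diagnostic only; it never switches the analysis to a nonparametric
  branch. Two-sided α = 0.05 throughout; no multiplicity correction.
* **ICC.** Variance-component intraclass correlation for the
  duplicate-measurement design; default form is two-way,
  absolute-agreement, single measurement — the standard test–retest
  choice — with a one-way random-effects form as a configurable
  alternative that doubles as a brute-force oracle. Reliability wording
  follows the conventional bands: <0.5 poor, 0.5–0.75 moderate,
  0.75–0.90 good (upper bound inclusive), >0.90 excellent.
* **CoV.** Per subject, `SD(pair)/mean(pair)·100` with
  `SD(pair) = |x₁−x₂|/√2`; reported as mean ± SD across subjects.
  Scale-invariant, not shift-invariant.
* **Bland–Altman.** Bias = mean difference; limits of agreement
  bias ± 1.96·SD of differences; (average, difference) coordinates are
  exported for plotting.
* Short-term reproducibility pairs the two same-day baselines, pooled
  over study days; long-term pairs the two days' baseline
  representatives (per the baseline policy).

## Synthetic cohorts

The generator emulates the tabular layer of a randomized two-day
crossover in healthy adults: per subject two room-air baselines and one
gas session per day, 100% O₂ on one day and 12% O₂ in N₂ on the other.
Presets encode the published group values of that design: baseline flow
indices (MV 71 ± 11 a.u. hyperoxia arm, 73 ± 9 hypoxia arm), corrected
saturations (96/64% and 96/66%), blood gases (pO₂ 95 ± 8 → 338 ± 44
and 96 ± 15 → 55 ± 4 mmHg), flow responses (−26 ± 12% and +9 ± 10%),
and saturation shifts (+1/+5 percentage points under hyperoxia;
−1.8/−1.2 under hypoxia — chosen inside the rounding bands of the
published integer levels so that the implied per-subject
content-difference change also matches its published −2% value).
Hemoglobin (14 ± 1.2 g/dL), per-vessel dispersions, vessel geometry and
the decomposition of measurement noise into session, vessel and day
components are not published; they are documented estimates chosen from
normal physiology, with the noise split back-calculated so the implied
test–retest CoV of extraction is ≈9.8%.

Model structure: the gas response is a single multiplicative flow
factor per subject applied coherently to MV, MT, MA and all per-vessel
MBR values (the published day profiles move all three ONH indices
together), plus additive per-subject saturation shifts drawn
independently of the baseline level. Saturations, hemoglobin and blood
gases are normal, truncated to physical ranges — with the truncated
*mean* matched to the target so that mass piling against the arterial
ceiling does not shift the group mean; flows and diameters are
moment-matched log-normal (positivity). Venous saturations are kept
strictly below arterial ones per session. All draws flow from one
master seed through a counter-based Philox stream, so tables are
byte-identical across runs and platforms.

The repeatability-pair generator is direct rather than pipeline-based:
true per-subject values are log-normal with a between-subject SD solved
from the preset's target intraclass correlation, and the two readings
are `t(1+ε)` with Gaussian relative error whose SD is solved from the
target mean CoV via the half-normal correction
`E[CoV] ≈ √(2/π)·c·(1+c²/2)` (the naive identification `c = CoV`
would understate the noise by ~25%). With multiplicative noise the
per-subject CoV is exactly scale-free, and the population intraclass
correlation has the closed form `σ_b²/(σ_b² + (μ²+σ_b²)c²)` used by
`implied_icc`. A consequence worth noting: the between-subject SD
implied by ICC 0.910 and CoV 9.8% at mean 43 a.u. is ≈18 a.u., larger
than the published cohort SD of 10 — the published ICC and CoV are not
simultaneously consistent with that SD, and the presets prioritize the
two reproducibility targets.

### What the generator does not emulate

Images and speckle statistics; cardiac-cycle waveforms; the reported
MBR–velocity saturation nonlinearity at high flow (not corrected in the
measurement model either); drop-out and fundus-quality exclusions;
correlations between saturation response and flow response within
subject (drawn independently); per-session systemic blood-gas values
(the subjects table carries one baseline set per subject, so the
systemic-pO₂ content source uses baseline values at all timepoints —
one more reason the saturation-derived source is the default). Passing
recovery tests therefore shows the pipeline and estimators are
unbiased under this generative model, not that the devices behave this
way in patients.

## Numerical choices and degenerate inputs

* Saturations are fractions internally, percent at every file
  boundary; CSVs are written with 10 significant digits (round trips
  lossless well beyond the guaranteed 6).
* Corrected saturations are clipped to [0, 1] with a logged warning
  rather than an error (robustness to extreme flux configurations).
* Sessions with no artery, no vein, or zero total venous flow are
  rejected by validation before any arithmetic; paired tests with zero
  difference spread return p = 1 (all-zero) or p = 0 (constant shift);
  zero-variance ICC and zero pair means raise explicit statistics
  errors.
* All aggregations are symmetric; vessel iteration order never affects
  results.

## Replication protocol sizes

The acceptance script uses 500 cohort replicates per gas arm at the
study sample sizes (21 and 22 subjects) and 200 replicates of 500
duplicate pairs for the reproducibility targets; the in-suite checks
use 100 cohort replicates and 30 pair replicates, with the type-I-error
calibration at its full 2000 replicates. These sizes put the
Monte-Carlo standard error of every recovered quantity well inside the
tolerance it is compared at.
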