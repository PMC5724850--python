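# Methods

## The biomarker

The density-mask emphysema score of a chest CT is

ES = 100 · |{ x ∈ L : I(x) < −950 HU }| / |L|,

the percentage of lung voxels L whose attenuation falls strictly below
−950 HU. Computed on the raw reconstruction (`origES`, in
`compute_orig_es`) it is a well-known but fragile biomarker: sharp
reconstruction kernels and thin slices add high-frequency noise whose
negative tail leaks below the threshold and can inflate the score by tens
of points, while smooth kernels and thick slices average genuine
emphysematous voxels above the threshold and deflate it.

The normalized score (`normES`, in `compute_norm_es`) applies three
harmonization steps before thresholding, in this order:

1. **z-resampling** (`resample_z`). The volume is modeled as a stack of
   piecewise-constant slabs of the native slice thickness and re-sliced at
   the target thickness (default 3 mm): each output slab is the
   overlap-weighted mean of the input slabs it covers. This models the
   averaging of a slice-sensitivity profile, is deterministic, exact when
   the slabs tile (6 × 1 mm → 2 × 3 mm reproduces block means), and is
   applied identically when thinning (1.25 → 3 mm) or thickening
   (5 → 3 mm). The output slab count is `round(extent / target)`, so the
   physical extent is preserved to within one slab. A mask resampled
   alongside is rebinarized at 0.5.
2. **kernel normalization** (`decompose_bands`, `measure_band_energies`,
   `apply_normalization`). The image is split into N difference-of-Gaussians
   frequency bands at physical scales σᵢ = σ₀·gᶦ⁻¹ (defaults N = 6,
   σ₀ = 1 mm, g = 2; filtering respects anisotropic spacing), plus a
   low-pass residual: I = lowpass + Σ bᵢ, which holds to ≤ 1e−4 HU by
   telescoping. Each band's *energy* — the population standard deviation
   of the band over the lung mask — is rescaled to a reference profile:
   Î = lowpass + Σ (Eref,i / Ei) · bᵢ, with the scale factors clamped to
   [1/4, 4] and a zero-energy band passed through unscaled. Energies are
   measured in-lung only, but the scaling is applied to the whole band
   grid to avoid seams at the lung boundary. The reference profile is the
   per-band median of in-lung energies over a set of scans reconstructed
   with the chosen reference kernel, measured *after* z-resampling — the
   same stage at which normalization runs in the scoring pipeline, so a
   scan normalized against its own profile is untouched.
3. **bullae filtering** (`filter_small_clusters`). Per axial slice,
   8-connected components of sub-threshold pixels with area strictly below
   5 mm² are discarded as noise (a component of exactly 5 mm² is kept,
   matching the strict "smaller than" reading of the rule). The unit is an
   area, so the filter is deliberately 2-D per slice rather than a 3-D
   volumetric rule.

Band filtering is implemented incrementally (each pyramid level smooths
the previous one by the residual σ), which equals direct filtering at the
full scales by the Gaussian semigroup property; kernels are truncated at
6σ so the two paths agree to ~1e−8 relative in the field interior.

The density threshold is strictly `< −950` (not ≤). HU values are clamped
to [−1100, 3200] on ingest and after normalization; the threshold is well
interior to this range, so clamping never moves the score.

## Lung segmentation

`segment_lungs` is a deterministic threshold pipeline: voxels below
−500 HU are air candidates; 6-connected components touching the in-plane
image border are removed as exterior air; components smaller than 50 ml
are dropped; the largest (up to 2) components are kept; a spherical
morphological closing of radius 2 mm and slice-wise hole filling smooth
the result. Airways are not removed and the lungs are not separated —
scores are whole-lung. On digital phantoms the Dice overlap with ground
truth exceeds 0.99; on real scans users with their own segmentation can
pass a mask file and bypass this module.

## Survival evaluation

Cohorts follow a case-control (two-phase) design: every death is kept,
survivors are subsampled with a known fraction f and carry sampling
weight 1/f. All estimators consume these weights, which makes weighting
the deterministic equivalent of "uniformly resampling" the survivor pool
back to full size; with integer weights the weighted Kaplan-Meier equals
the estimator on the correspondingly replicated cohort exactly (tested).

* **Kaplan-Meier / censoring distribution** — weighted product-limit
  estimator; the censoring curve Ĝ uses the inverted event indicator.
* **Percentile categories** — low / medium / high at the 60th and 80th
  weighted percentiles (linear interpolation); boundary values fall in
  the middle class. Pairwise weighted log-rank tests over the three
  classes are flagged at the Bonferroni threshold 0.05/3 ≈ 0.0167.
* **Time-dependent AUC** (`td_auc`) — the cumulative/dynamic estimator at
  horizon t: cases are subjects with an event by t, controls those still
  in follow-up beyond t; subjects censored before t enter neither set and
  are re-represented through inverse-probability-of-censoring weights
  1/Ĝ(Tᵢ⁻) for cases and 1/Ĝ(t) for controls, multiplied by the sampling
  weights. The AUC is the weighted fraction of case-control pairs ranked
  correctly by the marker, ties counting ½; it is computed by sorting,
  which equals the O(n²) pairwise sum exactly (tested against it).
* **AUC differences** — percentile bootstrap stratified by event status
  (preserving the case-control composition of every replicate); the
  package default is 6000 replicates, scaled to 500 in the demo.
* **Risk mapping for NRI** — a one-covariate Cox proportional-hazards fit
  per marker: Newton iteration on the weighted partial likelihood with
  Breslow tie handling (converged at |score| < 1e−8; the marker is
  standardized internally for stability) and a weighted Breslow baseline
  cumulative hazard; predicted risk at t is 1 − exp(−Λ₀(t)·e^{βm}). The
  fit matches lifelines' estimates to 1e−6 on tie-free unweighted data
  (tested).
* **Continuous NRI** (`continuous_nri`) — subjects move "up" (new risk
  higher) or "down" (exact ties in neither); event probabilities within
  the up/down classes come from weighted Kaplan-Meier at the horizon and
  are combined by Bayes' rule with the weighted class fractions:
  NRI = [P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)],
  reported in percent with a stratified bootstrap CI. Without censoring
  this reduces exactly to direct counting (tested). Identical markers
  give 0; swapping the markers negates the NRI exactly.
* **Cause-specific analyses** — for lung-cancer mortality, deaths from
  other causes are censored at the death time (the cause-specific
  convention); a competing-risks treatment is out of scope.

Horizon years convert at 365.25 days/year. All bootstrap procedures are
driven by one integer seed and are bit-reproducible.

## Synthetic data

The generators define the study conditions under which the package is
validated; they are first-class, tested code.

**Phantom** (`generate_phantom`): two ellipsoidal lungs (parenchyma
−860 HU with 40 HU Gaussian texture) inside a soft-tissue cylinder
(40 HU) in exterior air (−1000 HU); grid 64 × 96 × 96 at
1.25 × 1 × 1 mm. Emphysema is a set of non-overlapping spheres at
−995 HU with radii 3.5–9 mm placed uniformly inside the lungs — sizes and
depth chosen so that, as for real centrilobular lesions near the
threshold, the lesions survive clinically realistic slice averaging.
Ground truth (lung mask, lesion mask, exact emphysematous fraction) is
returned with the image.

**Kernel simulation** (`simulate_kernel`): appearance-level models —
soft = Gaussian blur (1.0 mm) + mild noise at 4 mm slices;
medium = light blur (0.5 mm) + moderate noise at 2 mm;
sharp = unsharp-mask boost (0.8 at 1 mm scale) + strong noise at 1.25 mm —
each followed by slab-averaging to its slice thickness. This reproduces
the band-energy signature that kernel normalization targets (sharp
renditions have several-fold higher fine-band energy, and origES inflates
by ~20–30 points on a sharp rendition) without projection-domain CT
physics. The medium kernel serves as the default reference: it sits in
the middle of the band-energy range, so normalization mostly attenuates
(sharp) or mildly amplifies (soft), keeping the clamped scale factors far
from their limits.

**Cohort simulation** (`simulate_cohort`): true emphysema extent follows
a right-skewed mixture (60% near-zero half-normal, 40% gamma); death
times are exponential with hazard λ₀·exp(0.30·trueES) and administrative
censoring just after seven years plus 5% uniform early drop-out; the
baseline hazard is calibrated so roughly 30% of subjects die before the
administrative end, matching a high-risk screening case mix. A quarter-ish
of deaths are lung-cancer deaths, with probability mildly increasing in
true emphysema. The case-control stage keeps all deaths and half the
survivors (weight 2). Observed origES adds a kernel-dependent bias and
noise; observed normES adds only small noise.

**End-to-end study** (`end_to_end_fixture`): 20 phantoms with varying
lesion burden are rendered under the three kernels and scored by the full
imaging pipeline; each of 2000 simulated subjects is assigned one
(phantom, kernel) pair, carries the *measured* origES/normES of that
rendition as markers, and dies at a rate driven by the phantom's true
emphysema extent. Because the phantom set carries more emphysema than the
parametric mixture, the fixture's baseline hazard is set lower
(1.2e−5/day) to keep the deceased share near 30%. Kernel assignment is
independent of survival, so any cross-kernel marker bias is pure,
outcome-irrelevant corruption — exactly the confounding a multi-protocol
study suffers.

### What passing tests show — and what they do not

The phantoms have no airways, vessels, fissures, gravity gradients, or
scanner-specific noise textures; kernel simulation is a blur/boost/noise
surrogate, not filtered back-projection; and the survival model is a
single-marker exponential. Passing tests therefore demonstrate that the
pipeline's *mechanics* are correct (conservation, identity, oracle
equivalence, weighting) and that the method removes exactly the kind of
kernel-driven corruption it is designed for — they do not certify
absolute score accuracy or prognostic value on clinical scans.

## Numerical choices and degenerate inputs

* Resampling weights are exact slab overlaps; with matching spacings the
  weight matrix is the identity and the output is voxel-identical.
* A band with zero in-lung energy passes through unscaled (warning).
* Scale factors clamped to [1/4, 4]; output HU clamped to the ingest
  range.
* Kaplan-Meier step factors are clipped into [0, 1] against float
  round-off when an entire weighted risk set dies.
* IPCW denominators are floored at 1e−12; horizons with no cases or no
  controls raise an error (the table driver simply omits such rows).
* The Cox fit refuses constant markers and reports non-convergence after
  100 Newton iterations rather than returning a bad estimate.
* Problem sizes in tests (phantom grids of 24–64 slices, cohorts of
  300–2000, 100k only for a closed-form reference, 500 bootstrap
  replicates in the demo versus the 6000 default) are chosen so the whole
  validation runs in minutes on one core while every check retains its
  statistical teeth.

## Known limitations

* No airway/trachea exclusion in segmentation — a small positive bias on
  whole-lung air fraction for real scans.
* Band-energy matching equalizes second-order statistics per band, not
  the full spectrum; a residual systematic offset between kernel
  renditions of a few tenths of a point of ES remains at default
  settings.
* One segmentation is computed per scan and reused; masks are not
  re-derived from the normalized image.
* DICOM reading handles single-series axial directories only; no oblique
  resampling, gantry-tilt correction, multi-frame DICOM, or DICOM
  writing.
* No competing-risks estimation, covariate adjustment, or multivariable
  risk modeling.
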