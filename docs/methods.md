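# Methods

This note records the models behind `cvrkit`, the defaults and why they
were chosen, what the simulators do and do not emulate, and the package's
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Stimulus model and regressor construction

The PetCO2 target is a piecewise-constant schedule: baseline `b` with
square hypercapnic blocks at `b + step`. Defaults — baseline 35 mmHg, step
+10 mmHg, blocks of 45 s and 130 s separated by 90 s of baseline — describe
a standard two-level sequential-gas-delivery challenge; the 35 mmHg
baseline sits at the typical normocapnic end-tidal level (cohort PetCO2
minima average near 35 mmHg), and the lead-in (60 s) and tail (fill to
255 volumes at TR 2 s, i.e. 185 s) are choices exposed in the protocol
config, since acquisitions differ in how much baseline they record around
the blocks.

Volume `i` is timestamped at its midpoint `t0 + (i + 0.5)·TR`. This
symmetric convention is fixed so tests can be bit-exact.

End-tidal extraction is automated (manual point-picking is not
reproducible): a breath's end-tidal point is the maximum of its expiratory
excursion, located with a peak finder constrained by a minimum inter-peak
interval (default 2 s ⇒ ≤ 30 breaths/min) and a prominence of 25% of the
trace's range; on flat plateaus the trailing edge is used, as it is the
sample closest to end-exhalation. A trace without respiratory oscillation
(range < 1 mmHg) is a detection error, not an empty result. Between
breaths the PetCO2 waveform is linearly interpolated onto volume midpoints
with flat extrapolation beyond the first/last breath — the simplest model
consistent with a slowly varying target.

A hemodynamic lag between PetCO2 and the BOLD response is not applied by
default. An optional global integer-volume lag (search window ±5 volumes,
chosen to maximize the mean in-mask fit r, ties resolved toward zero lag)
acknowledges the physiology without changing default behaviour.

## Voxelwise fit

For regressor `x` and voxel time course `y` (after QC), the reported
quantities are the OLS slope `b = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²`, the Pearson
correlation `r`, and `CVR = 100·b/S0` in % BOLD per mmHg. The percent
denominator `S0` is the mean signal over the normocapnic epoch (volumes
with regressor within 1 mmHg of the protocol baseline; all volumes if no
such epoch exists). A baseline-epoch mean is the physiologically standard
denominator for "percent signal change"; it is stated exactly so recovery
tests can demand machine precision.

Numerical/degenerate-input rules:

- a constant time course gets slope 0, r 0, and stays valid (avoids NaNs
  propagating into ROI means);
- voxels whose `S0` is at or below the signal floor (default 10⁻⁶ × the
  in-mask grand-mean absolute signal) are flagged invalid — air voxels must
  not produce enormous percent slopes;
- a zero-variance regressor is an error, not a map;
- `r` is clipped to [−1, 1] against floating-point overshoot.

QC is censoring by deletion, never interpolation: the first `n_discard`
volumes (default 3, magnetization equilibration) and an explicit censor
list are removed from BOLD and regressor in lockstep. The censor budget
(`max_censor`, default 9) fails loudly when exceeded. A censor list can be
derived from a 6-parameter motion table by thresholding framewise
displacement (default 0.9 mm; rotations scaled by a 50 mm head radius) —
a reproducible stand-in for visual review. Fewer than 10 retained volumes
is a QC failure. No spatial smoothing, slice-timing or motion registration
is performed: masks and motion estimates are inputs.

## ROI summarization

Tissue volumes are voxel count × voxel volume (cm³), independent of the
map. ROI CVR indexes are unweighted means over valid voxels. "Brain"
is GM ∪ WM: ventricular/CSF voxels show an artifactually negative apparent
CVR (vessel dilatation displaces CSF), so CSF is excluded from the
parenchymal average; the phantom encodes this with a negative ventricular
compartment and the mapping is required (by test) to recover its sign.
An ROI with zero valid voxels yields an absent index plus a warning.

## Cohort statistics

All tests are two-sided (sidedness is a convention, fixed once):

- **Normality gate** — Shapiro–Wilk; "parametric" iff p ≥ α (default
  0.05). The driver uses it per group to choose between a two-sample t and
  Mann–Whitney for group comparisons.
- **Mann–Whitney U** — exact null when `n1·n2 ≤ 400` and the data are
  tie-free, otherwise normal approximation with continuity and tie
  correction. The reported U counts (control > mtbi) pairs; the output
  notes the complementary convention `n1·n2 − U`.
- **Paired t** — visit-2 minus visit-1 differences within patients;
  zero-variance differences are reported degenerately (t = 0, p = 1 for
  zero mean; p → 0 with a flag otherwise) rather than erroring.
- **Pearson r** — pairwise-complete deletion; ≥ 3 pairs; zero variance is
  an undefined-correlation error.
- **Adjusted group effect** — additive OLS `response ~ group + age + sex`
  with type-II partial F per term, sex as a 0/1 indicator. "Analysis of
  covariance" admits several parameterizations; the additive model with
  partial tests is the standard reading, and the driver runs exactly one
  such model rather than guessing alternatives.
- No multiple-testing correction is applied (small exploratory cohorts
  rarely do); the report's meta row counts the tests performed so a reader
  can apply their own.

Subjects lost to follow-up are excluded only from paired analyses
(pairwise-complete handling throughout).

## Phantom generator

Nested-box geometry on a default 24×24×12 grid of 3.6×3.6×3.0 mm voxels:
background border, CSF rim, GM shell, WM core, and a small ventricular
pocket (CSF subclass) at the center. Margins shrink on smaller grids so no
compartment is empty. Every voxel follows

    S(t) = S0 · (1 + (c/100)·(PetCO2(t) − b)) + drift·t + ε(t),  ε ~ N(0, σ²)

with per-compartment `c` (healthy preset: GM 0.28, WM 0.160, CSF 0.05,
ventricle −0.10 %/mmHg; mTBI preset: GM 0.26, WM 0.1472), baseline signals
1000/800/600/500, and seeded noise. The generator returns the truth field,
so recovery tests are exact: with σ = 0 and drift = 0 the mapping must
reproduce `c` to < 10⁻⁸ per voxel and the tissue presets to < 10⁻⁶ after
summarization.

What the phantom does **not** emulate: anatomy, partial-volume mixing,
EPI distortion and dropout, physiological noise spectra (cardiac/
respiratory), motion beyond spike corruption, scanner drift structure
beyond a linear term. Passing recovery tests therefore demonstrates the
*estimator* is correct, not that real-data confounds are handled.

## Cohort generator

Subject-level variables (age, SCAT2, SSS, GM/WM/brain CVR, GM/WM volume,
PetCO2 min/max) are drawn from a latent Gaussian copula per group. Target
pairwise correlations encode the study structure — negative SCAT2–CVR
correlations in controls (≈ −0.56…−0.59, and age–SCAT2 ≈ −0.6), positive
SCAT2–CVR (≈ +0.4) and SCAT2–GM-volume (≈ +0.52) correlations in patients,
and a negative WM-CVR–WM-volume correlation (−0.46). Unspecified pairs are
0 and the completed matrix is projected to the nearest positive
semi-definite correlation matrix (eigenvalue clipping + diagonal
renormalization). The control SCAT2 row's joint loadings exceed unit norm,
so projection attenuates those targets (to ≈ −0.48…−0.52);
`effective_correlation()` exposes the operative matrix, and the large-n
convergence test asserts against it.

Visit-2 records for the follow-up subset are generated on the latent scale
as `z2 = ρ·z1 + √(1−ρ²)·e` with innovations from the same copula, then
mapped to the visit-2 marginals (GM volume mean 365.1 → 351.4 cm³). The
generic test–retest correlation ρ defaults to 0.7; the preset overrides it
to 0.95 for tissue volumes because volumetric MRI measures are highly
stable, and because the observed paired GM-volume decline (≈ −13.7 cm³,
n = 19, p ≈ 0.005) implies a difference SD near 19 cm³, i.e. ρ ≈ 0.92 —
a functional-measure ρ of 0.7 would make the decline underpowered, which
would misrepresent the longitudinal structure the preset exists to encode.

Marginals are Gaussian. SCAT2 is clipped to its defined 0–100 range (the
distortion is < 0.2% of the mean); SSS is *not* clipped at 0 because with
a control mean of 5.3 and SD 10.2 truncation would shift the mean by about
+2 and break the generator's own moment contract — occasional negative SSS
values are the price of exact first/second moments, and are documented
rather than hidden. Sex is assigned by exact counts per group
(`round(male_fraction·n)`, shuffled) by default so demographic percentages
are reproduced deterministically from counts; Bernoulli sampling is
available. Sex does not enter SCAT2 generation by default (the group
effect of sex is not significant in the adjusted model); age enters through
its negative latent correlation with SCAT2.

The full-group mTBI marginals and the follow-up subset's visit-1 marginals
are numerically identical in the preset, so a single preset covers both
readings of which sample the marginals describe.

## Pipeline and I/O

NIfTI grids must match exactly (dims + voxel size); mismatch is an error —
silent resampling is the classic neuroimaging footgun. Configurations are
strict (unknown keys rejected) and fully serialized; every run writes a
manifest with a config hash and the seed, and reruns are byte-identical.
Stage failures carry the stage name and subject id; partial outputs are
retained and listed in the manifest.

## Problem sizes used in validation

The test suite and acceptance script use: a 6×6×4×60 random series for
oracle equivalence against per-voxel `scipy.stats.linregress`; the default
24×24×12×255 noiseless phantom for preset recovery; 1000-replicate null
simulations (n = 50 for Shapiro–Wilk, 20 + 20 for Mann–Whitney) for type-I
calibration; 5000 subjects per group for copula convergence; and 200
seeded replicates at the preset sample sizes (18/25/19) for the
qualitative-structure check. These sizes make the whole suite run in
seconds while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- The CVR model is linear and lag-free by default; dispersive hemodynamic
  response shapes, nonlinear vasodilatory saturation and regional lag
  variation are not modeled.
- Masks, motion estimates and symptom scores are inputs; segmentation,
  registration and questionnaire scoring are out of scope.
- The Mann–Whitney exact path requires tie-free data; heavily tied data
  silently fall back to the corrected normal approximation (the method
  name in the result records which path ran).
- The cohort generator reproduces first/second moments and pairwise
  correlation structure, not distributional shape (skewed symptom scores,
  floor effects) or informative dropout; the follow-up subset is drawn at
  random.
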