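# Methods

## Signal model and T1 estimation

The acquisition model is the steady-state spoiled-gradient-echo (SPGR)
equation. At repetition time `TR`, nominal flip angle `α`, and relative
transmit field `b1` (effective angle `α_eff = b1·α`):

```
S = M0 · sin(α_eff) · (1 − E1) / (1 − E1 · cos(α_eff)),   E1 = exp(−TR/T1)
```

T1 and M0 are estimated by the DESPOT1 linearization: across flip angles,
`S/sin(α_eff)` is linear in `S/tan(α_eff)` with slope `E1`, so
`T1 = −TR/ln(slope)` and `M0 = intercept/(1 − slope)`. The linear fit is the
definition of correctness here: it is closed-form, deterministic, and inverts
the forward model exactly (to floating tolerance) for any T1 in the
physiological range at the protocol angles — the test suite checks T1 in
[100, 3000] ms to < 1e−6 relative error, with and without a B1 field.
No nonlinear refinement is layered on top.

Protocol defaults mirror the reference acquisition: TR 5.79 ms, flip angles
1°, 7°, 14°; echo times (2.46, 3.69 ms) are carried as metadata only. Angles
are degrees at every interface and converted to radians once, internally.

**Invalid voxels.** A voxel whose fitted slope falls outside (0, 1), or
whose signals are all non-positive, has no positive T1 consistent with the
model. Such voxels are marked NaN and counted, never clamped: a clamped
voxel would silently bias ROI means, while an excluded one is reported
(`T1Map.n_invalid`, `MaskedMean.n_invalid_excluded`). B1 correction is
applied per voxel by scaling the nominal angles with the measured relative
field; omitting it leaves a T1 bias that grows monotonically with |b1 − 1|,
which the suite verifies as an ablation.

## Segmentation and volumetry

Lesions are delineated as closed planar polygons on a subset of axial
slices (typically every second slice). Missing slices are filled by
shape-based interpolation: each bounding polygon is converted to a signed
distance field on a common fine grid (default step: half the finer in-plane
spacing, capped at 0.5 mm), the fields are blended linearly by slice
fraction, and the zero level set is extracted as the interpolated contour.
This is order-independent and, for convex bounds, produces cross sections
whose areas interleave between the bounding areas.

Rasterization uses the center-in-polygon rule with even-odd counting
(vertex orientation is irrelevant), so an axis-aligned 10×10 mm square on a
1 mm grid covers exactly 100 voxels. Volume is the per-slice segmented area
times the slice thickness, summed over slices — including interpolated
slices. Masked means are arithmetic means over valid voxels only, with the
excluded invalid-voxel count reported; a fully invalid ROI is an error.

## The reduction rate

`RR = (T1_plain − T1_HBP)/T1_plain` is computed mean-then-ratio: the masked
mean T1 is taken per phase, then the ratio of the two means. This matches a
per-lesion mean-T1 workflow and is *not* the mean of voxelwise ratios; on
grouped data the two orders differ (e.g. the ratio of the G1 group-mean T1s
is 0.4155 while the mean of per-lesion ratios rounds to 0.40), which the
tests document rather than hide. RR is invariant under common rescaling of
the two T1s, bounded above by 1, and may legitimately be negative (T1
lengthening), in which case it is flagged, not rejected.

## Immunoreactive score

OATP1B3 membranous staining is summarized as the product of a
percent-positive category and an intensity category:

* percent: 0 → 0; (0, 10%) → 1; [10%, 50%] → 2; (50%, 80%] → 3; > 80% → 4
* intensity: absent 0, weak 1, moderate 2, strong 3 (symbols 0/+/++/+++
  accepted)
* IRS = percent × intensity ∈ [0, 12], binned negative (0), low (1–3),
  medium (4–8), high (9–12).

Two boundary choices were genuinely open and are fixed as follows: exactly
10% positive cells falls in category 2 (the category-1 definition is a
strict "< 10%"), and the 50%/80% boundaries close the lower category
(50% → 2, 80% → 3) — the latter is forced by the reference cohort, where a
(50%, moderate) lesion is a medium-band case (2×2 = 4). No reference-cohort
lesion sits on the 10% boundary, so that choice affects no shipped fixture.

## Statistics

* **Summaries**: mean ± sample SD (n−1); median and quartiles by the
  weighted-average convention (position `(n+1)·p`, linear interpolation,
  clamped at the extremes). This convention reproduces the reference
  quartile brackets exactly.
* **Kruskal–Wallis**: tie-corrected H. The p-value is exact (full
  permutation enumeration, `p = P(H ≥ H_obs)`) when the pooled sample has at
  most 9 observations, asymptotic chi-square (k−1 df) otherwise; both routes
  are available explicitly via `method=`. The chi-square approximation is
  simply not trustworthy at n ≤ 8, which is why the small-sample default is
  exact. Post-hoc: rank-based pairwise z comparisons on the pooled ranking
  (Dunn-style) with Bonferroni adjustment over all pairs.
* **Mann–Whitney**: U counts pairs with ties contributing ½. Exact p by
  enumeration over all label assignments for pooled n ≤ 12, otherwise a
  normal approximation with tie-corrected variance (no continuity
  correction). The exact two-sided p is defined symmetrically,
  `P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|)`, which remains well defined under ties.
* **Wilcoxon signed rank**: differences after − before, zeros dropped,
  statistic W⁺. Exact by enumerating 2ⁿ sign assignments for n ≤ 15 (the
  one-sided `P(W⁺ ≤ w)` is exposed in `details`); tie-corrected normal
  approximation beyond. All pairs tied yields a flagged degenerate result.
* **ROC**: AUC via the midrank identity, equal to the normalized
  pairwise-comparison count with ties at ½; validated in tests against
  brute-force pair enumeration. The Youden cutoff evaluates
  J = sens + spec − 1 at every midpoint between adjacent distinct observed
  scores under the rule "score ≥ cutoff ⇒ positive"; J ties break toward
  maximal specificity, then the larger threshold. Operating-point metrics
  are percentages; ratios with empty denominators are `None`, never 0 or
  100. The positive class for grade discrimination is G1 (higher RR ⇒ more
  uptake ⇒ better differentiated).
* **Printed-precision comparisons** in tests round half-up to 2 decimals
  with ±0.01 tolerance, matching how tabulated values are printed.

## Synthetic data

Two deliberately independent test surfaces:

**Cohort simulation** draws RR directly per grade from a normal
distribution truncated above at 1 (defaults G1 0.40 ± 0.15, G2 0.26 ± 0.07,
G3 0.25 ± 0.07), IRS categories from the reference cohort's per-grade
frequencies (with a consistent percent/intensity pair sampled within the
drawn category), lesion volumes log-normal moment-matched to
mean 170.94 / SD 212.82 cm³, and growth patterns at their marginal
frequencies. Volume is drawn independently of RR; a grade-conditional
volume–RR correlation is not modeled because none is established.

**Phantom simulation** builds piecewise-constant T1 ground truth (liver
background 720.7/332.7 ms native/HBP; spherical lesions, default G1-like
950.2/555.4 ms), a separable smooth quadratic B1 bump scaled into the
requested range (default [0.85, 1.15] when enabled), and evaluates the SPGR
forward model voxelwise per flip angle and phase. Noise is Gaussian on the
magnitude by default, with a Rician option; at the SNRs exercised (≥ 50 at
the 14° volume) the Gaussian approximation is adequate and keeps the
oracles closed-form. All generators take explicit integer seeds; there is
no hidden global RNG state.

What the phantom does **not** emulate: partial-volume voxels at lesion
boundaries (tissue classes are crisp), respiratory motion and misalignment
between phases, coil-profile receive inhomogeneity, and spatially
correlated noise. Passing the end-to-end tests therefore demonstrates the
correctness of the estimation chain under the stated acquisition model, not
robustness to those real-world effects; the screening-eligibility table is
likewise synthetic per-lesion (only aggregate exclusion counts are known).

## Pipeline and reproducibility

`run_study_pipeline` is deterministic given config and inputs; reports are
serialized with sorted keys and contain both full-precision and
printed-precision (2-decimal half-up) values, a structured stage/lesion log
(including per-lesion invalid-voxel counts), and abort on any stage error
with the stage name and offending lesion id. Problem sizes used by the
default test run: phantoms of 24×24×12 voxels at 2×2×3 mm (20 seeds for RR
recovery), simulated cohorts of 100 lesions per arm (100 replicates for
discrimination recovery) — large enough for the stated statistical bounds,
chosen as the package's own test geometry.

## Known limitations

* The fit assumes ideal spoiling and a mono-exponential T1 per voxel; no
  MT/B0 effects, no slice-profile correction.
* Contour interpolation assumes the lesion's topology does not change
  between drawn slices (one polygon per slice).
* The asymptotic Mann–Whitney route omits the continuity correction, so
  different software may differ in the third decimal of borderline p-values.
* The embedded cohort stores values at printed precision; statistics that
  were originally computed from unrounded measurements (notably the AUC)
  cannot be reproduced from it exactly and are instead validated against
  enumeration oracles.
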