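# Methods

This note documents the models, conventions and numerical choices behind
`hubshift`, in the order data flows through the package.

## Montage and geometry

The layout is a schematic concentric-ring projection of the 10–20
system onto the unit disc: Cz at the origin, y > 0 anterior, x > 0
right; the outer ring (radius 0.90) holds Fp1/Fp2, F7/F8, T3/T4, T5/T6,
O1/O2 and the inner ring (radius 0.45) F3/F4, Fz, C3/C4, P3/P4, Pz. The
coordinate table is a versioned literal with exactly mirrored left/right
and front/back values, so mirror symmetry and the zero centroid of the
19 clustered channels hold to the last bit. No statistic in the package
depends on head geometry beyond symmetry and reproducibility; individual
anatomy and 3-D digitization are out of scope.

Twenty-one electrodes are recorded in the target setting but only 19
belong to the three analysis clusters (anterior 7, central 5, posterior
7). The two extras are taken to be the midline positions Fpz and Oz;
they are excluded from the default analytic set and can be included via
`standard_montage(include_unclustered=True)`. This choice is a
convention, not a claim — any 10–20 pair placed symmetrically would
serve, and the cluster definitions are unaffected.

## Preprocessing

Order of operations per epoch: common average reference → band-pass →
instantaneous phase. Re-referencing subtracts the instantaneous mean of
the analytic channel set. Band filtering is a brick-wall real-FFT mask
(bins with lo ≤ f ≤ hi kept, edges inclusive): linear, exactly
zero-phase, deterministic, and idempotent on already-filtered input.
Band defaults are delta 0.5–4, theta 4–8, lower alpha 8–10, upper alpha
10–13, beta 13–30 Hz; gamma is excluded because scalp gamma is not
reliably separable from muscle activity. Phase is the angle of the
frequency-domain analytic signal, computed per epoch with no edge
trimming: with 4096-sample epochs the edge region is a negligible
fraction of the sign statistics computed downstream, and fixed-length
epochs keep every later shape contract simple. Acquisition-time
settings of the target recordings (1 s time constant, 70 Hz low-pass)
are hardware filters and are not re-applied in software.

Note that brick-wall filtering assumes roughly bin-aligned content;
pure tones exactly at a band edge but off the FFT grid lose part of
their leakage mass. This is irrelevant for broadband EEG-like signals
but matters when constructing test fixtures, which therefore use
bin-aligned tones.

## Phase Lag Index

PLI = |⟨sign(Δφ)⟩| with Δφ the wrapped phase difference and
sign(0) = 0, evaluated per epoch and averaged across epochs. The sign of
the wrapped difference is computed as sign(sin Δφ), which is identical
for every Δφ except the measure-zero exact-antiphase point and avoids
explicit wrapping. Regional PLI averages all within-region channel
pairs (C(7,2)=21 anterior/posterior, C(5,2)=10 central); the
alternative "all pairs touching the region" reading of regional
averaging is available via `regional_pli(..., convention="touching")`.
The within-pair convention is the default because it makes regional
values independent of the other regions.

### Finite-sample null behaviour

For i.i.d. uniform phases each epoch's PLI is |mean of n signs|, a
half-normal with σ = 1/√n. Two properties matter in practice:

* **Epoch averaging does not lower the null level.** Averaging k
  per-epoch |PLI| values averages folded normals: the spread shrinks
  with k but the level stays ≈ 0.80 σ_epoch.
* **Band limiting inflates the null.** The sign process of the phase
  difference of two independent band-limited signals is serially
  correlated; empirically its effective sample count per epoch is about
  1.5 · B · T_epoch (B the bandwidth in Hz, T_epoch the epoch length in
  seconds), so the null median is ≈ 0.675/√(B·T_epoch). For the lower
  alpha band (B = 2 Hz) at 8.192 s epochs this is ≈ 0.17 — far above
  the broadband level (≈ 0.01), and the reason narrowband PLI values
  must always be compared against a band-matched null
  (`pli_null_quantiles(..., band=...)`).

The often-quoted "null floor below 0.1 at 4×4096 samples" holds for
broadband signals and for the wide beta band, not for the 2–3 Hz-wide
alpha bands.

## Spanning tree and betweenness centrality

The tree of strongest connections is built by Kruskal's algorithm on
edges sorted by descending PLI; equal weights are broken by ascending
(i, j) channel order so the output is deterministic (for all-distinct
weights it is the unique maximum-weight spanning tree under any
strictly decreasing weight transform). Betweenness centrality on a tree
is computed exactly in integer arithmetic: removing node v splits the
tree into components of sizes m_i, and the number of pairs through v is
C(N−1, 2) − Σ C(m_i, 2). The default normalization divides by
N(N−1)/2 — the total number of paths between any two nodes, following
the hub-strength definition used in the target analysis — while the
more common (N−1)(N−2)/2 convention is available via
`betweenness(..., denominator="interior")`. The two differ by the
constant factor (N−2)/N and cannot change any trend statistic's p-value,
only the scale of reported BC values.

## Hub-location statistic and head maps

The center of mass is the BC-weighted mean of electrode coordinates.
The normalization by ΣBC is deliberate: it is what makes "uniform BC ⇒
center exactly at Cz" true for every layout, whereas an unnormalized
dot product would need coordinates that sum to zero. The y component is
the primary statistic (front-to-back), x is secondary (left-right).

Head maps use biharmonic (thin-plate) spline interpolation with Green's
function g(r) = r²(ln r − 1) augmented with an affine term under the
standard orthogonality constraints, so the surface passes exactly
through the channel values and reproduces constant and linear fields
exactly. Maps are rendered on a 128×128 grid masked to the unit disc
with the mass center marked; rendering is purely for inspection and
never feeds statistics.

## Statistics

Trend models are mass-univariate OLS per (measure, band, region):
`outcome ~ intercept + β·group + γ·sex`, group entered as the ordinal
severity code 0–3, sex coded 0 = male / 1 = female; the p for trend is
the two-sided p on β. PLI and BC are ln(x + 1e−24)-transformed before
modelling (reported group means remain raw); center-of-mass coordinates
are signed and modelled untransformed. An omnibus multivariate test is
deliberately out of scope — the reported quantities are per-cell trend
p-values. If the sex covariate has zero variance in a cell it is
dropped (it carries no information and would otherwise make every small
fixture singular); genuine rank deficiency remains an error.

Multiplicity control is explicit and configurable. The trend tests use
a Bonferroni factor with default 4 (the number of groups), always
recorded in the result and the report. Family-wise control over a whole
band × region table additionally requires multiplying by the number of
cells; with 20 cells and factor 4 alone, a fully null cohort still
produces at least one flagged cell in roughly a fifth of runs — the
package's null-control tests therefore pass the family-wide factor
explicitly. MMSE correlations are two-tailed Spearman tests with the
threshold 0.05/n_tests, n_tests = bands × regions × measures ×
AD-groups = 120 (→ 0.00042) within groups or 40 (→ 0.00125) with the
AD groups merged, reported rounded to five decimals; the ×2 measures
factor (PLI and BC) is what produces those printed thresholds.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis consumes,
not the physiology of EEG. Per band and region, a band-limited Gaussian
driver is shared by the region's channels; channel i receives it
rotated by a fixed phase offset θ_i = 2π f_c τ_i (f_c the band center,
τ_i = 5 ms × the channel's within-region rank) and mixed as
κ·driver + √(1−κ²)·private noise; a 1/f-weighted broadband floor of
relative amplitude 0.3 and a 10 µV overall scale complete the channel.
The phase rotation rather than a literal time delay is intentional: for
the narrow analysis bands the two agree to first order, and the
rotation makes the κ = 1, noise-free limit give PLI exactly 1 (a
literal delay suffers occasional phase slips at amplitude nulls).
Zero-lag (unrotated) sharing would be invisible to PLI by construction,
which is why a zero lag is rejected when the simulation parameters are
constructed.

Defaults mirror the emulated study: four epochs of 4096 samples at
500 Hz, 19 analytic channels, group sizes (133, 105, 96, 117) for
controls/mild/moderate/severe, per-group MMSE means 28.5/25.8/21.5/15.4
(SD 1.3/1.6/1.1/3.5, clipped to 0–30) and female fractions
0.63/0.38/0.54/0.53. Reproducibility: one master seed, with each
subject drawn from an independent substream keyed by (seed, group,
within-group index), so a subject's data is invariant to the cohort's
group sizes.

Because published group levels are empirical PLI values, not generative
parameters, the map κ → mean PLI is inverted numerically:
`calibrate_coupling` bisects κ, evaluating each candidate by simulating
subjects restricted to the target band (the brick-wall bands are
disjoint, so this is statistically equivalent in-band) and running the
full analysis path including the common average reference. Evaluations
reuse fixed per-subject seeds (common random numbers), making the map
deterministic and monotone. The re-reference caps the attainable
regional mean below 1 (≈ 0.92 at κ = 1); targets at or above the cap
clamp to κ = 1 with a warning, targets below the band's null floor are
an error. Default: 16 subjects per evaluation, tolerance ±0.01. The
study preset calibrates the posterior lower-alpha cell to the control
level (0.274) and severe level (0.238) and interpolates the per-step
severity slope linearly; all other cells keep a flat κ = 0.35
(a mid-range resting-state coupling level that yields regional PLI
around 0.15–0.2, with no severity dependence, matching the absence of
reported trends elsewhere).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: artifacts (blinks, muscle, ECG),
nonstationarity, realistic cross-frequency or cross-region coupling
structure, volume conduction, between-subject biological variability of
coupling (within-group PLI spread is finite-sample noise only, ≈ 0.02,
versus ≈ 0.1 in real cohorts), and any true anatomical hub
architecture. The emergent forward hub shift under posterior coupling
decline is a consequence of tree topology, not a modelled mechanism.

## Problem sizes and determinism

The test suite uses the study's own conditions where the claim demands
them (50-subject calibration checks; 20 replicate cohorts at the full
group sizes for severity-trend recovery; 50 subjects for epoch
stability) and small cohorts elsewhere; the full suite runs in roughly
ten minutes on one CPU. All stochastic tests run under fixed seeds, and
the pipeline guarantees byte-identical outputs for identical config and
seed. EDF round trips are exact to within half a 16-bit quantization
step of the per-channel physical range.

## Known limitations

* The brick-wall filter's circular-convolution edge effects are left in
  (no trimming); negligible at 4096-sample epochs but not for very
  short epochs.
* The BC normalization and the regional-averaging convention used by
  the original analysis software cannot be recovered from the emulated
  study's text; both options ship, defaults as documented above, and
  every run logs its choices.
* `calibrate_coupling` assumes the target band's null floor and cap
  bracket the target; for very narrow bands and short epochs the
  attainable window can be narrow.
* The EDF writer emits plain EDF (not EDF+); covariates ride in the
  local-patient-identification field.
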