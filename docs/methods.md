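# Methods

## Measurement model

MFI% treats the mean T1 signal of a muscle region as a fraction of the mean
signal of subcutaneous fat on the same slice. On single-echo T1-weighted
images fat and water signals are not chemically separable, so the ratio is a
*relative* fat-infiltration index, not a proton-density fat fraction; its
virtue is that any global linear scaling of scanner units cancels
(`mfiquart` asserts this scale invariance in its tests). No intensity
preprocessing (bias-field correction, windowing) is applied before
measurement.

A measurement unit is (subject, lumbar level, side, quartile). For each
level one axial slice is annotated with, per side, one muscle ROI
(multifidus and erector spinae outlined together) and a small fat-reference
ROI. When two fat references exist, each side normalizes to its ipsilateral
one; with a single reference both sides share it (logged per measurement).
A missing muscle ROI skips that side with a warning; a missing fat
reference is a hard error.

## Coordinates, rasterization

Pixels are addressed 0-based as (row, col) with centers at integer
coordinates. A pixel belongs to an ROI iff its center lies inside the
polygon (even-odd rule). Centers exactly on the boundary are resolved by a
half-open convention — the test point is nudged by +1e-7 in both row and
col, making top/left edges inclusive — so two ROIs sharing an edge never
both claim a pixel. Rasterization is validated against a brute-force
crossing-number oracle on random star polygons. DICOM rescale
slope/intercept are applied at read time; MFI% is unaffected by them but
stored fixtures stay comparable.

## Quartile partition

Quartiles are defined on **pixel counts**, not geometric width. Pixels are
projected onto a medial→lateral unit axis, sorted ascending with a
deterministic tie-break (projection, then row, then col), and cut into four
contiguous blocks of size ⌊N/4⌋ or ⌈N/4⌉ with the `N mod 4` larger blocks
placed medially. Q1 is most medial, Q4 most lateral; Qmean is the
unweighted mean of the four quartile MFI% values (it equals the whole-ROI
value exactly when N is divisible by 4; the whole-ROI value is separately
available via `whole_roi_mfi` for diagnostics).

The medial→lateral axis is, by default, the in-plane image-column axis
signed per side: under radiological display (patient left on image right)
lateral is (0, −1) for the right side and (0, +1) for the left; the
orientation flag inverts both. How the original in-house tools of this
field order pixels (column, distance from a manually set midline, principal
axis) is generally not documented, so the axis convention is explicit and
recorded in every CLI run's provenance block; a mask-principal-axis
alternative (sign-aligned to the column axis) is available behind
`axis="principal"` for sensitivity analysis.

Two subtleties of the fixed tie-break worth knowing: reversing the axis
maps quartile i to 5−i only when no group of equal-projection pixels
straddles a block boundary (ties are ordered identically under both
directions), and the remainder pixels always attach to the *new* medial
end. Both are consequences of determinism, not bugs; the tests pin them
down.

## Agreement statistics

The primary estimator is the single-measure absolute-agreement ICC under
the two-way model `y_ij = μ + s_i + r_j + e_ij` (rows = units, columns =
repeated measurements):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

The reliability literature often labels two-way designs "ICC(3,1)" while
describing absolute agreement; since the classical ICC(3,1) is the
*consistency* form, this package makes the choice explicit: absolute
agreement is the default (it penalizes systematic rater offsets) and the
consistency form is available via `form="consistency"`.

The two-sided CI uses F quantiles with a Satterthwaite degrees-of-freedom
approximation: with `a = k·ρ̂/(n(1−ρ̂))`, `b = 1 + k·ρ̂(n−1)/(n(1−ρ̂))`,

    v     = (a·MSC + b·MSE)² / ((a·MSC)²/(k−1) + (b·MSE)²/((n−1)(k−1)))
    lower = n(MSR − F₁·MSE) / (F₁·(k·MSC + (kn−k−n)·MSE) + n·MSR),  F₁ = F_{1−α/2}(n−1, v)
    upper = n(F₂·MSR − MSE) / (k·MSC + (kn−k−n)·MSE + n·F₂·MSR),    F₂ = F_{1−α/2}(v, n−1)

α defaults to 0.05 (two-sided). Identical columns over non-constant rows
give ICC = 1 with a degenerate (1, 1) interval; a fully constant matrix has
zero total variance and raises an explicit error. Classification follows
the Portney–Watkins bands, half-open lower-inclusive: < 0.50 poor,
[0.50, 0.75) moderate, [0.75, 0.90) good, [0.90, 1] excellent.

**Known limitation of the CI.** Simulation shows the interval holds its
nominal 95% coverage at moderate n (e.g. 94.5% over 2000 tables at n = 30,
k = 2, true ICC 0.8 with non-zero rater variance) but *undercovers* when k
= 2, the rater variance is non-zero and n is large (≈75% at n = 200 with
variance components 9/0.5/1): the interval narrows ∝ 1/n while the single
rater-pair draw (MSC has k−1 = 1 degree of freedom) keeps contributing
estimator variance. This is a property of the standard F/Satterthwaite
construction itself — an independent implementation (pingouin) shows the
same coverage — and is inherent to designs with very few raters, not a
defect of this implementation.

Bland–Altman analysis reports the mean difference, its n−1-denominator SD,
and limits of agreement at the conventional 1.96 multiplier. For published
limits (fixed-precision decimals) `implied_mean_difference` recovers the
midpoint using decimal arithmetic on the printed representations with
half-away-from-zero rounding, avoiding binary-float artifacts at exact
.5 midpoints.

### Pairing and strata

Intra-rater matrices pair session 1 with session 2 per rater and stack all
raters' rows; inter-rater matrices pair rater 1 with rater 2 within one
session (the first, by default; configurable and recorded). Units with
incomplete pairs are dropped and counted, never silently. The stratified
report produces every level × quartile cell, each quartile pooled over
L1–L5, each side per level and pooled, and an overall pool. The overall
stratum pools Q1–Q4 rows only — Qmean is derived from them and would
double-count — and pooling heterogeneous units (different levels, sides,
quartiles) as independent rows inflates between-row variance, which narrows
pooled CIs; stratum-level estimates are the honest granularity.
Strata with too few complete pairs are flagged in a `status` column rather
than dropped.

## Sample-size planning

The Walter–Eliasziw functional approximation with `C_j = 1 + kρ_j/(1−ρ_j)`:

    n = 1 + 2k(z_α + z_β)² / ((k−1)·ln²(C0/C1))

with one-sided normal quantiles, ceiling-rounded (a fractional subject is a
whole subject). The canonical design (ρ₀ = 0.75, ρ₁ = 0.95, k = 2,
α = 0.05 one-sided, β = 0.20) yields n = 10. Designs requiring more than
10⁶ subjects raise an infeasibility error. n is weakly decreasing in the
effect gap, in α and in β (property-tested).

## Phantom generator

The phantom emulates what the measurement needs and nothing more: a
160×160, 1 mm grid; two elliptical muscle compartments (~1800 px each,
64-vertex polygons) flanking the midline; two circular fat references;
background 40, muscle base 300, fat 1000 (so a fat-free muscle reads
MFI% = 30, the scale seen in healthy paravertebral muscle); quartile fat
fractions defaulting to (0, 0.2, 0.4, 0.6) medial→lateral; additive
Gaussian noise SD 10 (≈ SNR 30 for muscle; set 0 for exact fixtures).
Muscle intensity is a linear two-compartment mixture
`(1−f)·base + f·fat`, with f a step function over four equal-count lateral
slabs, so the expected quartile MFI% has a closed form that the pipeline
must recover exactly on noise-free input. It is a simulation convention
consistent with T1 fat hyperintensity, not scanner physics; it omits bias
fields, partial-volume mixing at tissue interfaces, anatomical texture and
through-plane effects, so passing tests demonstrate correctness of the
*computation*, not robustness to real-image artifacts.

Rater behavior is simulated as vertex displacement along the local outward
normal (redrawn, bounded, until the polygon stays simple), optional
per-rater systematic bias, and additive measurement noise in MFI% units.
The full-study simulator gives each subject its own severity by shifting
all four fat fractions by a common subject offset (SD 0.08, clipped to
[0, 1]), producing genuine between-subject variance so ICCs are
well-defined. A separate null-model generator draws two-way tables
`y = μ + s_i + r_j + e_ij` with chosen variance components and attaches the
theoretical ICC as metadata. All randomness descends from one user seed
through named independent substreams (image noise, jitter, tables, study).

## Numerical and design choices

- Fat-reference guard: the fat mean must exceed 1e-6 × the slice maximum,
  else a named normalization error (prevents division blow-ups on
  pathological fixtures).
- ROI interchange is a versioned, purpose-built JSON schema (kind, side,
  vertices per ROI; subject/level/rater/session at the top level) because
  the field's in-house annotation tools have no shared published format;
  DICOM-RT and volumetric formats are out of scope (the method is
  single-slice).
- Measurement CSV: exact header
  `subject_id,level,side,quartile,rater_id,session_id,mfi_percent`,
  quartile ∈ {Q1..Q4, Qmean}, unique on the six key columns, full float
  precision round-trip.
- Simulation sizes in the shipped tests (subjects, replicate counts, grid
  sizes) were chosen as the smallest designs whose Monte-Carlo error is
  comfortably below the asserted tolerances.

## Known limitations

- Separating multifidus from erector spinae, curved/fascicle-following
  axes, cross-sectional-area or volumetric outcomes and fat/water
  separation are out of scope.
- Exactly two raters are supported for inter-rater analysis (the common
  reliability design); generalized multi-rater coefficients are not.
- The CI undercoverage regime described above applies to any k = 2 design
  with material rater variance and large n.
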