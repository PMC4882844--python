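# mfiquart

Quartile-based quantification of **muscle fatty infiltration (MFI%)** in the
lumbar paravertebral muscles (multifidus + erector spinae) on axial
T1-weighted MRI, with the complete reliability-assessment toolkit used to
validate such a measurement: absolute-agreement intraclass correlation
coefficients with confidence intervals, Bland–Altman limits of agreement,
reliability classification, and ICC sample-size planning.

## Who this is for

Researchers studying paraspinal muscle quality (low back pain, disc
degeneration, sarcopenia) who measure fatty infiltration from manually drawn
regions of interest (ROIs) on single-echo T1 images, and who need the spatial
*medial-to-lateral distribution* of fat — not just a whole-muscle average —
together with defensible intra-/inter-rater reliability statistics.

## The method

For each lumbar level L1–L5, one axial slice at the inferior end-plate is
annotated with a bilateral muscle ROI and a small subcutaneous-fat reference
ROI. The muscle ROI's pixels are sorted along the medial→lateral axis and cut
into four **equal-pixel-count quartiles** Q1 (most medial) … Q4 (most
lateral). Each quartile's mean T1 signal is normalized by the fat reference
from the same level:

```
MFI%_q = 100 · mean(S_muscle,q) / mean(S_fat),     Qmean = (MFI%_Q1 + … + MFI%_Q4) / 4
```

Fat is hyperintense on T1, so MFI% rises with fat content, and the ratio
cancels any global scanner scaling.

Reliability of repeated measurements (two raters × two sessions) is
summarized by the single-measure absolute-agreement ICC under the two-way
model `y_ij = μ + s_i + r_j + e_ij`:

```
ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))
```

with an F-based 95% CI (Satterthwaite degrees of freedom), classified as
poor (< 0.50), moderate (0.50–0.75), good (0.75–0.90) or excellent (≥ 0.90),
plus Bland–Altman mean difference and limits of agreement `d̄ ± 1.96·s_d`.
Study planning uses the Walter–Eliasziw approximation for the number of
subjects needed to distinguish a null ICC ρ₀ from an expected ICC ρ₁.

Because clinical cohort images cannot be redistributed, the package ships a
**phantom generator**: synthetic axial slices with bilateral elliptical
muscle compartments carrying known quartile-wise fat fractions, fat
reference regions, image noise, and simulated rater-boundary jitter — so the
whole pipeline and all statistics are exercisable end to end.

## Worked example

```python
from dataclasses import replace
from mfiquart import (PhantomSpec, RaterSimSpec, generate_phantom,
                      quantify_slice, simulate_reliability_study, AgreementStudy)

# a noise-free phantom with fat fractions (0, 0.2, 0.4, 0.6) across Q1..Q4
ph = generate_phantom(replace(PhantomSpec(), noise_sd=0.0), level="L3", seed=0)
for m in quantify_slice(ph.slice, ph.rois):
    print(f"{m.side:>5} {m.quartile:>5} {m.mfi_percent:7.2f}")
```

```
 left    Q1   30.00
 left    Q2   44.00
 left    Q3   58.00
 left    Q4   72.00
 left Qmean   51.00
right    Q1   30.00
...
```

With muscle base signal 300, fat 1000 and fraction f, the expected value is
`100·((1−f)·300 + f·1000)/1000` — e.g. f = 0.2 gives 44.00 — and the
measured quartiles recover it exactly, increasing medially→laterally.

```python
# simulate a 10-subject, 2-rater, 2-session reliability study with 1 px
# boundary jitter, then fit the intra-rater agreement model
table = simulate_reliability_study(
    n_subjects=10, levels=("L3",),
    rater_sim=RaterSimSpec(boundary_jitter_sd=1.0, measurement_noise_sd=0.5, seed=7),
    seed=11)
print(AgreementStudy(table, design="intra").fit().summary())
```

```
Agreement study (intra-rater, ICC form: agreement)
==========================================================
units (Q1-Q4 pooled): 160   measurements/unit: 2   dropped incomplete: 0
ICC = 0.985  95% CI (0.979, 0.989)  -> excellent
Bland-Altman: mean diff = 0.332, SD = 2.983, LoA = (-5.515, 6.178), n = 160
...
```

An ICC of 0.985 with a tight CI says boundary jitter of ~1 pixel barely
perturbs the quartile MFI% values; increasing the jitter SD degrades the ICC
monotonically (see `tests/test_phantom.py`).

The same workflow is available from the shell:

```sh
mfiquart phantom --out data --subjects 2 --raters R1,R2 --sessions S1,S2 --jitter-sd 0.5
mfiquart quantify --images data --rois data --out results
mfiquart reliability --table results/measurements.csv --out results/reliability
mfiquart samplesize --rho0 0.75 --rho1 0.95 --k 2 --alpha 0.05 --beta 0.20
# n = 10
```

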