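# Methods

## The design and the model

`scanrel` analyzes a crossed scan–rescan design: each subject is scanned
twice on each of several scanners, volumes are extracted per (segmentation
software, structure) cell, and every statistic is computed per cell. The
working model for one cell is the two-way crossed random-effects layout with
replication

    value_ijk = μ + s_i + r_j + (sr)_ij + ε_ijk

with subject effects `s_i ~ (0, σ²_s)`, scanner effects `r_j ~ (0, σ²_r)`,
subject×scanner interaction `(sr)_ij ~ (0, σ²_sr)` and scan–rescan
(replicate) error `ε_ijk ~ (0, σ²_ε)`. Scanners are treated as a random
sample of scanner/protocol combinations throughout, so conclusions
generalize beyond the three devices at hand.

Two policy defaults are hard-wired but overridable:

* **Agreement and bias tests use raw volumes.** ICC and the omnibus scanner
  tests are computed on unnormalized volumes so that an imperfect head-size
  normalization cannot masquerade as (dis)agreement. `pivot_ratings` warns
  if handed a normalized table; the pipeline logs a warning when the ICC
  stage is forced onto normalized volumes.
* **Variance components, SEM/SDC and power use TIV-normalized volumes**
  (volume / intracranial volume), the common cross-sectional practice.

## Agreement: ICC(A,1) and ICC(C,1)

Both coefficients come from the two-way mean squares of the subjects ×
raters matrix without replication (raters = the two runs of one scanner, or
the scanners' first-run values):

    ICC(C,1) = (MSR − MSE) / (MSR + (k−1)·MSE)
    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

The consistency CI transforms the exact central-F interval for MSR/MSE with
(n−1, (n−1)(k−1)) df; the agreement CI uses the Satterthwaite-approximated F
procedure. Single-measurement (not average-measure) forms are used
because a clinical measurement is one scan. Between-scanner ICC is reported
per scanner pair (the natural reporting unit) and for all scanners jointly;
neither is privileged. Negative estimates are reported as computed — never
floored — and classify as "poor". Classification boundaries are
lower-inclusive: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9
excellent (0.9 itself counts as excellent; the conventional wording is open
on the boundary, so the choice is documented here).

Missing data are handled by listwise deletion per ratings matrix: a subject
missing any cell of the requested comparison is dropped and counted
(`dropped_subjects`), and row count + dropped count always equals the
declared design size. Between-scanner comparisons default to first-run
values; a run-mean policy exists for sensitivity analysis. The same
first-run convention is used for the between-scanner ANOVA (the natural
companion of the first-run ICC-C; configurable).

## Variance components

Balanced cells use the expected-mean-squares method of moments
(`σ̂²_ε = MS_E`, `σ̂²_sr = (MS_AB − MS_E)/r`, `σ̂²_r = (MS_B − MS_AB)/(a·r)`,
`σ̂²_s = (MS_A − MS_AB)/(b·r)`). Unbalanced cells (a missing run) are fitted
by REML — Fisher scoring on the four variance parameters with an active-set
rule pinning boundary components at zero, convergence tolerance 1e-8, at
most 500 iterations, on SD-standardized data for conditioning. On balanced
data the REML optimum coincides with the moments estimators at interior
solutions, which the tests verify to 1e-6 (and beyond); an independent
mixed-model implementation (statsmodels MixedLM with crossed variance
components) serves as a cross-check oracle in the test suite. Negative
moment estimates are truncated at zero and flagged.

**Interaction handling.** The SEM equations name only a scanner variance
σ²_r and a residual σ²_ε, but a crossed design also carries σ²_sr. The
interaction perturbs between-scanner comparisons while leaving scan–rescan
repeatability untouched, so the default folds it into the reported scanner
term (`sigma2_scanner = σ̂²_r + σ̂²_sr`). Alternatives
(`pool_into_residual`, `drop`) are available as a sensitivity switch.

## SEM and SDC

    SEM_within  = 100 · √σ²_ε / V̄            (percent of the cell mean V̄)
    SEM_between = 100 · √(σ²_r + σ²_ε) / V̄
    SDC         = 1.96 · √2 · SEM            (constant 2.771859…)

SEM_within is the noise floor of a single scanner; SEM_between adds the
scanner-associated variance and therefore can only be larger (guaranteed
after truncation). The SDC is the smallest within-person change
distinguishable from measurement error with 95% confidence. Percent-of-mean
reporting makes all outputs invariant to global rescaling of volumes and
TIVs. Lesion-filled and non-filled tables are analyzed as separate cells.

## Systematic bias

Normality of the double-centered within-subject residuals is screened with
Shapiro–Wilk at α = 0.05 (a constant cell passes vacuously, with a
warning). If normal: one-within-factor repeated-measures ANOVA with
Greenhouse–Geisser correction (a conservative default given only three
levels; toggleable). Otherwise: Friedman. Post-hoc pairwise tests match the
omnibus family (paired t / Wilcoxon signed-rank), run when the omnibus p
falls below a configurable gate (default 0.05), and are Bonferroni-corrected
over the scanner pairs within the cell — no correction across structures or
software, matching per-cell reporting. The choice of normality screen and
sphericity correction is recorded in each result's metadata rather than
claimed as canonical.

Bland–Altman statistics per scanner pair: bias = mean(A−B), limits of
agreement bias ± 1.96·sd(A−B), t-based CIs (SE of a limit:
`sd·√(1/n + 1.96²/(2(n−1)))`), and proportional bias as the slope of A−B on
(A+B)/2. Zero-variance differences leave the slope undefined; it is
reported as 0 with a `degenerate` flag.

## Power planning

Group sizes for a two-sided, equal-variance two-sample t-test detecting a
`delta_pct` percent difference (defaults: 1%, α = 0.05, power 0.80) are
found by exact search over the noncentral-t power function (bracket +
bisection; floor n = 2); the z-approximation `2(z_α/2+z_β)²σ²/δ²` is
available for reference. The within-scanner SD is `√(σ²_s + σ²_ε)` and the
between-scanner SD `√(σ²_s + σ²_r + σ²_ε)`, in percent of the mean, with
the subject variance taken from the same cell's VCA (overridable). The
reported ratio uses the integer sample sizes; the continuous variance ratio
is also emitted.

## The synthetic cohort generator

All effects are multiplicative mean-one lognormal factors:

    volume(i,j,r,s) = mean_s · head_i · subj_is · bias_js · inter_ijs · noise_ijrs

* `head_i = TIV_i / mean(TIV)` is a shared head-size factor (lognormal, CV
  `tiv_cv`); TIV is constant across scanners and runs for a subject. Because
  volumes and TIV share this factor, dividing by TIV removes head-size
  variance — as normalization does in real cohorts — and `subject_cv` is
  exactly the anatomical between-subject CV that survives normalization.
  The coupling can be switched off.
* `bias_js` are fixed multiplicative scanner biases (e.g. 0.97 = 3% low).
* Subject factors are drawn independently per structure.

A lognormal model keeps volumes positive and matches the percent-of-mean
error metrics; on the log scale it is exactly the additive crossed normal
model, so closed-form truths exist for parameter-recovery tests:
`σ²(log) = log(1+cv²)` per factor, and fixed scanner log-biases contribute
their (J−1)-denominator variance to the expected scanner component
(`log_scale_truth`). On the raw scale the variance components are still
estimated directly, mirroring the analysis pipeline.

**Preset design** (`preset_study_design`): 21 subjects × {GE, Philips,
Toshiba} × 2 runs, 11 structures, one missing record (first subject's GE
rescan, emulating a motion-artifact exclusion), GE gray matter ×1.02 and GE
white matter ×0.97. Free parameters, chosen once as field-plausible values
and not tuned: structure means (brain 1.05×10⁶ mm³ … accumbens 950 mm³),
between-subject CVs (brain 4.6% — the value consistent with needing roughly
600+ participants per group to detect a 1% brain-volume difference under a
~4.4% between-scanner SEM; DGM 7–12%), replicate-noise CVs (0.4% brain …
3% CSF/accumbens; small aggregates are easy to segment, CSF and small
deep-gray structures are not), interaction CV 1%, TIV 1.55×10⁶ mm³ with 4%
CV. Draw order is fixed and independent of the missing-record list, so
deleting a run never perturbs the remaining values.

**What the generator does not emulate:** segmentation failures and outliers,
lesion effects on segmentation, cross-software TIV discrepancies (one
software per config), proportional (volume-dependent) scanner bias, scanner
drift over time, and non-lognormal heavy tails. Passing tests therefore
demonstrate the statistical machinery is correct under the assumed error
structure, not that any particular software/scanner combination attains
these numbers on patients.

## Numerical choices and degenerate inputs

* SDC/SEM constant `1.96·√2` uses the literal 1.96 (convention), as do the
  Bland–Altman limits.
* All-equal data: variance components are all zero (no error), the omnibus
  test returns statistic 0 / p 1, ICC on identical columns is 1.
* Ratings matrices require ≥ 3 complete subjects and ≥ 2 raters; variance
  decomposition requires ≥ 3 subjects, ≥ 2 scanners, ≥ 2 runs.
* ICC denominators of zero raise an explicit undefined-ICC error.
* Negative variance estimates: truncated at zero (flagged); negative ICCs:
  reported as computed.
* Writer emits reals with 6 significant digits, which round-trips exactly;
  pipeline CSVs use 10 significant digits and are byte-reproducible for a
  fixed seed.

## Simulation sizes used in the test suite

Calibration tests use the preset design restricted to the structure under
study: type-I error of the omnibus test on 500 zero-bias replicates
(expected in [0.03, 0.07] at α = 0.05; Greenhouse–Geisser makes it mildly
conservative), detection of the planted 3% GE WM deficit on 500 replicates
(≥ 95% with the correct sign), parameter recovery on 500 balanced cohorts
(3 Monte-Carlo-SE band, with REML ≡ moments verified on a subset), CI
coverage of ICC(A,1) on 1000 21×2 matrices at true ICC 0.9, and empirical
power of returned sample sizes over 2000 simulated trials. These sizes give
Monte-Carlo standard errors comfortably inside each acceptance band.

## Known limitations

* The crossed model assumes homogeneous residual variance across scanners;
  a scanner with noisier protocols inflates the pooled σ²_ε rather than
  being attributed individually.
* REML with three scanner levels estimates σ²_r on 2 degrees of freedom —
  expectedly noisy; pairwise Bland–Altman biases are the more interpretable
  per-pair quantity.
* Friedman/Wilcoxon fallbacks lose power at n ≈ 21; with three levels the
  Greenhouse–Geisser correction is mild but not exact.
* No longitudinal (rate-of-change) analysis: the pipeline is deliberately
  cross-sectional, and percent-brain-volume-change methods are out of scope.
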