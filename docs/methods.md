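# Methods

## The problem

Preclinical factorial studies — here, an 8-arm mouse design crossing an
MPTP lesion factor with herbal-extract treatment (none / *Centella
asiatica* / *Withania somnifera* / both) — are usually reported with a
single control-versus-rest comparison. The Complete Comparison Display
(CCD) instead reports **every** pairwise comparison: for K groups,
K(K−1)/2 branches arranged as a staircase next to the bar chart, each
branch carrying three p-values.

## The comparison engine

### Assumption screening

Each group's sample (one group × one endpoint) is screened with three
normality tests:

- **Shapiro–Wilk** W (n ≥ 3),
- **Anderson–Darling** A² with mean and sd estimated from the sample,
  using a continuous p-value approximation rather than critical-value
  brackets,
- **Kolmogorov–Smirnov** against N(x̄, s). Because the null parameters
  are estimated from the same data, the plain KS null is strongly
  conservative (empirical size < 0.03 at nominal 0.05 in our
  calibration); we therefore use the **Lilliefors-corrected** null by
  default and keep the uncorrected variant available for comparison.

The three binary outcomes combine into one verdict by a configurable
rule. The default, `any` (any single rejection ⇒ non-normal), is the
most conservative reading of a protocol that routes *any* doubt about
normality to the nonparametric branch; `majority` and `all` are
provided. Two graphical diagnostics accompany the battery: a
standard-normal QQ plot at plotting positions (i − ½)/n and a histogram
with fitted normal overlay.

Each pair of groups is screened with **Levene's test** (mean centering;
the median-centered Brown–Forsythe variant is an option). Variances are
"similar" when p > α.

### Test selection

| both samples normal? | variances similar | variances dissimilar |
|---|---|---|
| yes | Student t (pooled, df = n₁+n₂−2) | Welch t (Satterthwaite df) |
| no  | Mann–Whitney U | **Welch's U**: Welch t on pooled midranks |

Welch's U is a rank-transform answer to the nonparametric
Behrens–Fisher problem: pool the two samples, assign midranks (ties get
the average of the ranks they straddle), split the ranks back, and
apply Welch's t. Ranks are assigned within each pair only, because the
whole procedure operates per combination of two groups. All p-values
are two-sided. The Mann–Whitney p is exact (full enumeration, via the
exact null distribution) when the combined n is at most 20 and there
are no ties; ties or larger samples use the normal approximation with
tie and continuity corrections. Degenerate inputs (zero variance where
a test needs spread) raise typed errors rather than returning NaN, so
the display can annotate "n/a".

### Family adjustments

- **Tukey HSD** over all K groups: studentized-range p with pooled
  within-group variance (df = N−K); unequal group sizes use the
  Tukey–Kramer standard error. At K = 2 this reduces exactly to the
  pooled t-test (q = √2·|t|).
- **Dunnett two-tailed**: the staircase supplies the control
  assignment. The tier anchored at group *g* compares *g* with every
  group displayed after it, so that tier is one Dunnett family with *g*
  as control — the only reading under which all K(K−1)/2 branches have
  a well-defined Dunnett value. The adjusted p for comparison *i* is
  the equicoordinate probability P(maxⱼ |Tⱼ| ≥ |tᵢ|) under the central
  multivariate t induced by the shared control (correlation
  λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), df = family N − K). We evaluate it by
  Monte-Carlo with 100 000 draws by default, conditioning on the
  control variate and the pooled-variance draw so that only a smooth
  product of normal-CDF differences is averaged; this brings the MC
  standard error well below 10⁻³ at the default draw count. A
  single-comparison family is computed in closed form (2·tₛf), so the
  last tier is exact. Draws are seeded per tier from the analysis seed;
  reruns are bit-identical.

A note on orderings: the Tukey-adjusted p uses the *all-group* pooled
variance while the displayed pair test uses only the two samples, so
the Tukey p is not guaranteed to exceed the pair p for every pair of a
heteroscedastic dataset; it does dominate the two-sided t computed on
the same pooled-variance scale, which is the meaningful monotonicity.

### Displayed first value

The figure caption convention puts "Student's t" first among the three
values per branch, but the protocol itself prescribes the adaptive
test. The package displays the adaptively selected test's p by default
(with the test name recorded in the exported table) because that
preserves the assumption protocol; a strict mode
(`strict_student_t=True`, CLI `--strict-student-t`) always shows the
pooled Student t instead.

Significance is boundary-inclusive: p = 0.05 exactly counts as
significant, and branches are drawn dotted exactly when the Tukey p is
at or below α.

## The figure

Left panel: one bar per group at its mean with sd error bars (sample
sd, n−1 denominator), every raw observation drawn as a short horizontal
line at its value, sample size printed under each bar, a solid
light-blue under-axis line spanning the lesioned groups (black for the
vehicle groups) and a dotted line under the extract-treated groups.
Right panel: the staircase, groups on the x-axis in display order,
tier i holding branches from group i to each later group at strictly
increasing heights (a simple global level counter — branch (i,j) and
(j,k) can never share a slot), three p strings under each branch
(selected / Tukey / Dunnett, "<0.001" floor, 3 significant digits).
Group display order is always input order; nothing is ever sorted.

SVG is the determinism surface: the SVG hash salt is pinned and date
metadata stripped, so identical inputs give byte-identical files. PNG
and PDF are also supported.

## Synthetic data

The generator emulates the 8-arm design: group mean = baseline +
lesion effect (lesioned groups) + recovery shift (lesioned, treated) or
unlesioned extract effect. Defaults — n = 6/group (a typical rodent
cohort), baseline 100, sd 10, lesion effect −30 (−3 sd), recovery 20
(centella) / 15 (withania) / 15 (both) — encode a large lesion deficit,
partial single-extract recovery, and a non-additive combination that
does not beat the better single extract. Noise families: normal;
standardized lognormal (zero mean, unit variance, right-skewed); and
contaminated normal (1−ε)·N(0,σ²) + ε·N(0,(5σ)²) with ε = 0.1 as the
non-normality stressor. Ordinal endpoints (swim score 0–3) come from a
latent-threshold model: the continuous draw is cut at equally spaced
thresholds spanning the range of true cell means ± one sd.

What the generator does **not** emulate: unequal real-world per-group
attrition, measurement floors/ceilings of the actual assays,
between-assay correlation, or the study's true (unpublished) per-group
sample sizes and variances. Passing calibration therefore demonstrates
the procedure's behaviour under its stated assumptions, not the
distributional quirks of any particular wet-lab dataset.

## Calibration harness and problem sizes

`simulate_procedure_calibration` replays the full
pretest-then-test-then-adjust procedure on replicate studies and
reports per-pair rejection rate, the primary-contrast rejection rate,
Tukey family-wise error, and how often each of the four tests was
chosen. The family-wise hit is computed by comparing the maximum
studentized statistic to the α critical value (evaluated once per run),
which is decision-identical to adjusting every pair and thresholding.

Problem sizes used by the shipped validation: 2000 replicates for the
null-size calibration (per-pair rejection stays in [0.03, 0.08] and
family-wise error in [0.03, 0.07] despite the pretesting), exhaustive
enumeration of all 2026 tie-free Mann–Whitney configurations with
combined n ≤ 10, a 10⁶-draw independent max-|t| Monte-Carlo for the
Dunnett oracle, 500 replicates for effect recovery and 200 for the
non-additivity pattern.

## Known limitations

- The Dunnett adjusted p is Monte-Carlo (except single-comparison
  tiers); values carry ~10⁻³ noise at default draws. Doubling draws
  changes adjusted p by < 0.005.
- Pretesting inflates the per-pair size slightly above nominal in
  small samples; the calibration harness quantifies this rather than
  hiding it.
- The exact Mann–Whitney path requires tie-free data; ordinal endpoints
  (heavy ties) always use the corrected asymptotic path, which is
  approximate for very small groups.
- No paired/repeated-measures support; groups are independent by design.
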