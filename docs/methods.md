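# Methods

This note documents the models and procedures `twinmeth` implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## The study design being modelled

Monozygotic twin pairs discordant for type 2 diabetes, with promoter
methylation measured on a 27K-style array (beta values in [0, 1] at ~27,000
CpG sites) in skeletal muscle (11 pairs) and subcutaneous adipose tissue
(5 pairs). Because co-twins are genetically identical, the paired
T2D − nonT2D difference isolates acquired methylation changes; the paired
design also removes chip batch effects when co-twins share a chip.

## Synthetic twin methylomes

### Generative model

For probe *j*, pair *i*, twin *k*:

1. component *c\_j* ~ Categorical(w_low, w_mid, w_high);
   baseline *b\_j* ~ Beta(a\_{c\_j}, b\_{c\_j});
2. pair level *m\_ij* = *b\_j* + N(0, σ\_pair), shared by both co-twins;
3. twin value *x\_ijk* = *m\_ij* + N(0, σ\_ind), plus the injected effect
   δ\_j/100 for the affected twin at nominated probes, truncated to [0, 1].

Sharing the pair baseline — not an explicit correlation parameter — is
what produces the strong co-twin similarity. Truncation is plain clipping
on the beta scale (not a logit transform); this is a transparency
simplification and slightly inflates mass exactly at 0 and 1 for extreme
probes.

### Calibration (done once, then frozen)

The skeletal-muscle defaults are
w = (0.64, 0.23, 0.13), Beta shapes (2.5, 30), (10, 10), (30, 2.5),
σ\_pair = 0.03, σ\_ind = 0.075. They were chosen analytically/by direct
simulation *before* the test suite existed, to meet the stated marginal
structure: ~64% of probes averaging below β = 0.25, ~13% above 0.75, and a
mean within-pair Pearson r ≈ 0.95 (measured 0.639 / 0.130 / 0.954 over 20
seeds at 2,000 probes × 11 pairs). The adipose defaults shift the weights
to (0.65, 0.20, 0.15), use σ\_ind = 0.055 (higher co-twin similarity,
r ≈ 0.97) and 5 pairs.

One structural trade-off cannot be avoided with beta-scale noise: σ\_ind
fixes *both* the co-twin correlation and the promoter intra-pair
difference spread. Calibrating to r = 0.95 yields a pooled SD of absolute
intra-pair differences of ~5.9 percentage points, somewhat above the ~4
points reported for promoters in the motivating study. The correlation and
the tail fractions were prioritised. Tests that need a paired-difference
SD of exactly 5 points (the power-analysis world) use a dedicated
configuration with σ\_ind = 0.05/√2.

### Phenotypes

Per-status means/SDs: BMI 30.2 ± 6.3 (nonT2D) vs 32.3 ± 6.4 (T2D) kg/m²
and HbA1c 6.0 ± 0.5 vs 7.7 ± 1.4 % follow the published twin
characteristics. The 2-h OGTT glucose (8.5 ± 1.5 vs 15.0 ± 3.0 mmol/l) and
clamp glucose-infusion rate (6.0 ± 2.0 vs 3.5 ± 1.5 mg·kg⁻¹·min⁻¹) are
shown only graphically in the source material, so clinically realistic
values were stated once here: the non-diabetic co-twins of discordant
pairs are mostly glucose-intolerant (hence 2-h glucose near the IGT range)
and T2D twins are insulin-resistant (lower GIR). Co-twin values share a
pair-level factor giving within-pair correlation 0.6, typical of adult MZ
anthropometry.

### Repetitive elements

LINE1 (8 CpGs), D4Z4 (9) and NBL2 (8) panels are generated per pair with
an intra-pair difference scale
s\_i = base + coupling·|ΔBMI\_i| + N(0, 1.5) for LINE1 (floored at 0.5)
and s\_i = base + N(0, 1.5) for the uncoupled tandem repeats. Both co-twins
share a site/pair level and add N(0, s\_i/√2), so the within-pair
difference has SD s\_i. Defaults base = 16, coupling = 1.5 points per
kg/m² give pooled |difference|-SDs of ~13.8 (LINE1) and ~9.7 (D4Z4/NBL2)
versus ~5.9 for promoters, reproducing the reported repeats-vs-promoters
ordering (≈13 / 10 / 4). The model-implied correlation between per-pair
LINE1 SD and |ΔBMI| is ~0.52 at large n — the reported 0.77 from 11 pairs
cannot be matched simultaneously with the ~13-point LINE1 level, because
an SD estimated from 8 sites is intrinsically noisy; 0.77 lies well inside
the sampling interval of an 11-pair estimate when the true value is 0.52.

### Clone tables

Bisulfite-sequencing validation data are n\_clones = 12 Bernoulli colonies
per CpG: methylated counts ~ Binomial(12, p\_site). The amplicon summary is
the unweighted mean of per-site percentages.

## Probe QC

Two "bisulfite-treated" reference strands are built by character
substitution — C→T (forward) and G→A (reverse), N preserved — and each
probe sequence is scanned against both; a probe is uniquely aligned iff it
hits exactly one start position in total. The scan is exact by default
(C-speed substring search) with an optional mismatch budget
(position-by-position comparison, intended for desk-scale references);
this deliberately replaces a gapped aligner because the criterion of
interest is uniqueness, not alignment score. Exclusion order is
multi-alignment first, then SNP-in-CpG among survivors (a SNP on either
base of the interrogated dinucleotide); dispositions are asserted to
partition the input on every run. Detection-P masking is inclusive at the
threshold (a cell with P = 0.05 exactly is treated as a failed
measurement).

Generated manifests embed each probe's 50-bp genomic segment once in a
synthetic reference (twice for multi-flagged probes); the probe sequence is
the forward conversion of its segment, mirroring the unmethylated
bead-type design, so the QC aligner genuinely recovers the planted flags.

## Global patterns

- **Tail fractions** classify per-probe mean beta with *strict*
  inequalities (< 0.25, > 0.75); values at a threshold are intermediate.
  All-missing probes are excluded and counted.
- **ANOVA**: every non-missing (probe, sample) value is one observation in
  `beta ~ pair + status + pair:status`, fitted by OLS with sequential
  (type I) sums of squares in that factor order. Note that under the
  synthetic model the pair *main* effect is null by construction (per-pair
  offsets are independent across probes and average out); pair-level
  structure appears in the co-twin correlation, and constructed inputs
  with global pair levels drive the pair F as expected.
- **Intra-pair variation** is the SD of |T2D − nonT2D| in percentage
  points. Per-pair scope: SD across a probe set within one pair (the
  quantity plotted against phenotype discordance). Pooled scope: SD over
  all pairs × probes (the headline repeats-vs-promoters comparison). The
  absolute value is taken before the SD, making the statistic invariant to
  twin labelling. Probes with any missing pair are dropped (complete-pair
  rule) and counted. The test behind the repeats-vs-promoters comparison
  is not uniquely determined by its description; a two-sided F-ratio test
  is provided and labelled as an interpretation.
- Correlations are Pearson throughout (Spearman behind a flag).

## Differential methylation

Paired differences are 100·(β\_T2D − β\_nonT2D) per complete pair; probes
with fewer than 2 complete pairs are excluded and logged. The per-probe
test is the one-sample t on differences (two-sided); an all-zero vector is
t = 0, P = 1; zero variance with non-zero mean is signalled as degenerate.

**Westfall–Young maxT.** "Permuting sample labels" in a paired design
reduces to within-pair label swaps, i.e. sign flips of per-pair
differences applied jointly across probes (preserving inter-probe
correlation). Step-down variant by default: probes ordered by |t|,
successive maxima of permuted |t| from the least significant rank upward,
monotonicity enforced; single-step (global max) selectable. Exhaustive
enumeration of all 2^n flips whenever 2^n ≤ 4,096 (n ≤ 12 pairs — both
study designs), exact tail proportions; otherwise B sampled flips with the
(b+1)/(B+1) estimator so no adjusted P is zero. Probes with missing pairs
keep their complete-pair statistic under every flip (a flip on a missing
pair is a no-op); the conservative alternative of dropping incomplete
probes from the family is a flag. Because the permutation distribution is
discrete, the adjusted P is finally clipped from below by the parametric
raw P to guarantee the adjusted ≥ raw invariant. Ties in |t| are handled
with a 1e-12 comparison slack so exact re-realisations of the observed
statistic count as exceedances.

## Power

Minimal detectable difference: smallest δ with
power(δ) = P(|T| > t\_{1−α′/2, n−1}) ≥ 0.80, α′ = α/m (Bonferroni), T
noncentral-t with noncentrality δ√n/SD; solved by bracketed bisection
(Brent) to 1e-6 points and reported unrounded and rounded to whole points.
The exact noncentral-t computation is essential at small df: with n = 5
and the genome-wide Bonferroni level the normal approximation is wrong by
tens of points. scipy's noncentral-t tails can underflow to NaN at extreme
noncentrality; non-finite terms are replaced by their exact limit (0 for
the opposite tail). The solver was verified against R's `power.t.test` to
1e-6 and round-trips against the package's own Monte-Carlo simulation.
The six canonical solutions are 4.69, 9.67, 17.46 (n = 11; m = 1, 136,
26,850) and 8.41, 30.76, 115.87 (n = 5) percentage points at SD = 5; the
last value rounds to 116, one point below the figure printed in the
motivating study — a discrepancy attributable to that software's
noncentral-t internals and within the documented ±1-point tolerance.

## Validation and enrichment

Validation comparisons are one-sided paired t-tests (the direction fixed a
priori by the array finding; with 3 pairs, 2 df). Gene-set enrichment is a
one-sided Fisher exact test (over-representation) on the 2×2 table of
differentially methylated vs other genes, inside vs outside the set,
restricted to array-represented background genes; set members absent from
the background are dropped with a warning, inputs are de-duplicated, and a
gene counts as differentially methylated when at least one of its probes
has raw P < 0.05. P-values are intentionally not adjusted across sets and
the result object says so. Whether the original pathway software tested
one- or two-sided is not recoverable; one-sided over-representation is the
conventional choice.

## What a green test does not establish

The synthetic world reproduces marginal and pairing structure, not
biology: no CpG-island vs shore geography, no cell-type composition
effects, no probe-type chemistry biases, no batch structure, and
independent probes (no spatial co-methylation). Real-data effect sizes and
the specific genes of the motivating study require its deposited data
(GEO GSE38291) and are explicitly out of scope; the suite establishes that
the estimators are correct and calibrated on a world with the stated
statistical structure, not that they would reproduce any particular
biological finding.

## Numerical conventions

- Missing values: literal `NA` in files, `NaN` internally; β = 0 is a
  legitimate value and never a sentinel.
- All genomic offsets 0-based; TSS distances signed (negative upstream).
- Differences reported in percentage points, T2D minus nonT2D.
- Every stochastic routine takes an explicit integer seed
  (`numpy.random.default_rng`); identical seeds reproduce byte-identical
  outputs, and stochastic claims are averaged over ≥ 20 seeds where the
  acceptance-level checks require it.
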