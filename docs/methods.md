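# Methods

This note documents the statistical model behind `lesionexpr`, the
choices made where the design was genuinely open, and what the synthetic
studies used for validation do and do not establish about real data.

## Probe-set annotation quality scores

A probe set *s* with probes q₁…qₙ is scored against every gene *g* that at
least one of its probes matches:

- **sensitivity(s, g)** = |{q : q matches g}| / n. Probes matching no gene
  at all count in the denominator — they are failed probes of the set.
- **specificity(s, g)** = Σ_{q matches g} 1/k(q) ÷ |{q : q matches ≥1 gene}|,
  where k(q) is the number of distinct genes q matches. A probe unique to
  *g* contributes 1, a probe shared with one other gene ½, and so on.
  The denominator counts only probes that match *something*: a failed
  probe says nothing about cross-hybridization. If no probe matches any
  gene the score is 0 with a warning.
- **weight(s, g)** = (sensitivity + specificity)/2, the semi-sum, always
  in [0, 1].

The 1/k down-weighting is the simplest rule that equals 1 for unique
probes and decreases with promiscuity; published annotation-quality
databases use proprietary variants, and we make no attempt to reproduce
their exact numbers — the scores here are defined by the two formulas
above and validated against literal probe enumeration. Gene symbols are
trimmed and case-folded before comparison because array annotation files
are inconsistent about casing.

## Panel filtering and aggregation

The analysis panel (in the motivating application, 369 curated
epithelial-identity and mammary-remodeling genes) is restricted to genes
with at least one scored probe set on the platform; drop counts are
reported (on the two GeneChips of the motivating datasets this yields
361 and 329 analyzed genes).

Gene-level expression is computed from the probe-set × sample log2 matrix
in one of two modes:

- **literal** (default): value(g, j) = meanₛ weight(s, g) · x(s, j) over
  the gene's probe sets — the weighted values are averaged as-is. This
  shrinks genes measured only by low-quality probe sets toward 0.
- **normalized**: Σₛ w·x / Σₛ w, a proper weighted mean that leaves a
  single-probe-set gene unchanged regardless of its weight.

Literal is the default because the procedure being modeled takes the
plain mean of weighted values; the normalized mode is exposed because the
shrinkage of the literal rule is a real attenuation bias (see
*Validation* below). Missing probe-set values are excluded pairwise; a
probe set annotated to several panel genes contributes to each with its
own per-gene weight. All expression is treated as log2-scale; a
`log2_transform` flag on the readers covers linear-scale files (values
must be strictly positive).

## Differential expression

For a contrast case-vs-reference the per-gene summary is the log2 fold
change Δ = x̄_case − x̄_ref with a 95% Student-t interval:

- **unpaired** (default): pooled-SE interval on n₁+n₂−2 df; p-value from
  one-way ANOVA restricted to the two classes, F on (k−1, N−k) df. For
  two classes F = t², which the tests assert to 1e−10.
- **paired**: the per-patient differences dᵢ = case − reference give
  Δ = d̄, SE = sd(d)/√n on n−1 df, and a two-sided one-sample t p-value.
  Requires patients with exactly one sample in each class.

Both study designs that motivate the package are patient-matched, so a
patient random effect is expected; the unpaired ANOVA is then valid but
conservative (the patient effect inflates the within-class variance but
cancels in the class-mean difference), while the paired analysis removes
it. Both modes are exposed; the simulation-based validation uses the
paired mode since the generator plants patient effects.

Degenerate inputs follow explicit conventions: identical data give F = 0,
p = 1; zero within-class variance with distinct class means gives the
smallest representable positive p with a `zero_variance` flag; a zero-SE
or df < 1 interval is reported as not determined (`ND` in output files).
Genes with fewer than two usable samples in a class (or fewer than two
complete pairs) get an ND row with reason `too_few_samples` and are
excluded from the multiple-testing adjustment rather than dropped.

Multiple testing uses the Benjamini–Hochberg step-up adjustment
(q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j, capped at 1), applied per contrast across all
testable genes of that contrast; each lesion therefore has its own
significant-gene list, matching how the motivating study reports separate
lists per lesion. Significance is strict: q < cutoff, default 0.1.

## Overlap classification

Significant-gene lists are compared as normalized symbol sets: exact
intersection and differences, alphabetically ordered, with duplicate
symbols deduplicated under a warning. When fold-change estimates are
supplied, shared genes with opposite signs are flagged as discordant
(the "changed in a similar manner" check). A subset test (A ⊆ B, with
the missing genes) supports precursor-hierarchy claims such as the ADH
list being contained in the DCIS list.

## Synthetic studies

The generator emits complete studies — probe-set matrix, probe-level
match table, design, panel and truth — from:

x[ps, j] = μ_g + a_ps + b_i + δ_{g,c} + ε[ps, j]

with gene baseline μ_g ~ N(8, 1) (typical log2 intensity scale),
probe-set offset a_ps ~ N(0, 0.3²), patient effect b_i ~ N(0, 0.5²)
shared by all samples of patient i, planted effect δ = ±2.0 log2 units
for DE genes in non-reference classes (0 otherwise), and noise
ε ~ N(0, 0.5²). Defaults mirror the paired design of the motivating HELU
study: 8 patients × {TDLU, HELU}, 369 panel genes, 1–3 probe sets per
gene (the motivating datasets average ≈2.3 and ≈1.9 probe sets per gene),
8–11 probes per set, 10% of probes cross-hybridizing to a second mapped
gene, 8/369 of panel genes without probe sets, and 30 planted effects.
A {HN, ADH, DCIS} triplet layout generates the matched three-class
design; the planted effect is applied to both lesion classes. One seeded
generator stream drives every draw, so identical parameters give
byte-identical studies.

What the generator does *not* emulate: array spatial artifacts, batch
effects, intensity-dependent variance, probe-sequence-driven biases, or
a realistic effect-size distribution (the planted ±2.0 is a strong,
convenient signal). Passing simulation checks therefore demonstrate the
correctness and calibration of the statistical machinery under the
stated Gaussian random-effects model, not performance on deposited array
data.

## Validation choices and known limitations

- **FDR control** is checked over 200 replicate paired studies (360
  genes, 10% non-null, 8 pairs) under the full generative model,
  including cross-hybridization; the mean empirical FDR sits near the
  nominal 0.1.
- **CI coverage and effect recovery** are checked with clean annotation
  (no promiscuous probes, one probe set per gene). This isolates the
  estimator property being tested: with promiscuous probes the semi-sum
  weight drops below 1 and the *literal* aggregation mode attenuates the
  planted effect by the mean weight — an intended consequence of the
  weighting rule, not an estimator defect. Users who need unbiased fold
  changes under imperfect annotation should use the normalized mode.
- Problem sizes in the test suite (e.g. 5,000 genes for coverage, 200
  replicates for FDR, 60 for the null Monte-Carlo budget check) were
  chosen to make Monte-Carlo error small relative to the asserted
  tolerances while keeping the suite quick to run.
- The panel manifests used in examples and tests are synthetic: the
  curated panel of the motivating study is not published as a machine-
  readable list, so bookkeeping checks plant the known unmapped counts
  (8 and 40 of 369) in generated studies.
- The published-profile fixture is a transcription of printed results
  and inherits their reporting: ND confidence bounds, one gene absent
  from one platform, one FDR given only as a bound (taken at the bound),
  and one apparent misprint (a CI not containing its estimate) kept
  as printed.
- Variance estimation is per gene with no shrinkage across genes;
  with 8 pairs the per-gene variance is noisy, which is visible in the
  simulations as occasional wide or ND intervals. Moderated
  (empirical-Bayes) testing is deliberately out of scope.
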