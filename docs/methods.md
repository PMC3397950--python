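# Methods

## Scope and data model

The package implements the computational chain of a methylation-biomarker
study of cervical neoplasia: tiling-array enrichment calling (discovery),
candidate-gene triage, QMSP quantification via the M-index, and ROC-based
marker evaluation (pre-validation). All genomic coordinates are 0-based
half-open; tabular interchange is TSV with a header, intervals are BED, and
evidence lists are one gene id per line.

## Tiling-array enrichment calling

**Centering.** Each array's probe log2 ratios are centered by subtracting the
Tukey biweight mean: starting from the median with scale fixed at the MAD,
observations are reweighted by `(1 − u²)²` for `|u| < 1` with
`u = (x − m)/(c·MAD)` and the location is iterated to convergence
(`c = 5`, tolerance 1e−6; the median is returned when the MAD is zero).
With `c = 5` a gross outlier beyond five MADs receives zero weight, so on
heavy-tailed data the estimate sits with the bulk, typically at or below the
median rather than between median and mean. Centering is shift-equivariant,
so region calls are invariant under adding a constant to all ratios.

**Windowed one-sided KS score.** For each probe, the *window* is every probe
on the same chromosome whose interval midpoint lies within ±250 bp of the
probe's midpoint (window width 500 bp), and the *background* is every other
probe on the whole array — the global reading of "the rest of the array".
The statistic is `D⁺ = sup_x [F_background(x) − F_window(x)]`, which grows
when window values shift upward. The probe score is −log10 of the one-sided
p-value; probes whose window holds fewer than `min_probes_per_window`
(default 2) probes score 0 and are counted in the log.

**Exact p-values.** Under the permutation null, `D⁺` depends only on the
window's ranks in the pooled sample. Three regimes:

- pooled sample small enough that `C(m+n, m) ≤ 200,000`: full enumeration of
  label assignments, exact including ties;
- window size ≤ 10 with distinct pooled values: an exact lattice-path count
  of rank sequences `r_1 < … < r_m` below the boundary implied by the
  observed integer statistic `K = max_i [m·C_i − n·(i−1)]` (cumulative-sum
  dynamic program, all-integer arithmetic whenever the binomial coefficient
  fits in int64, memoized across probes);
- otherwise the asymptotic one-sided bound `exp(−2 D⁺² mn/(m+n))`.

With the default 100 bp probe spacing and 500 bp window, production scoring
always hits the exact lattice path (5-probe windows against ~10⁴
backgrounds), which agrees exactly with full enumeration and with an
independent exact implementation of the one-sided two-sample KS test on every
instance tested. Exactness gives the calibration guarantee
`P(score ≥ s) ≤ 10^(−s)` per probe on exchangeable null data.

**Region calling and annotation.** Qualifying probes (score ≥ 2.0 by
default) merge into a region when the gap between consecutive qualifying
probes (next start minus previous end) is at most `merge_gap` (default =
window width); regions keep the maximal member score as `peak_score` and are
dropped below `min_probes_per_window` supporting probes. A gene is enriched
when any called region overlaps its promoter interval by ≥ 1 bp; duplicate
hits collapse to the best score. The score cutoff applies per probe (a
per-region-maximum mode is available through the config).

No multiple-testing correction is applied beyond the score cutoff — the
method thresholds the windowed-KS score directly.

## Candidate triage

The funnel is pure, order-invariant set logic with an audited partition at
every stage: cancer-specific genes `(SCC ∩ AC) \ Normal`; intersection with
the union of two external evidence lists (expression-down and tissue-specific
DMRs), recording which matched; re-expression confirmation at fold ≥ 2.0 in
≥ 1 cell line (both configurable — published re-expression thresholds are
rarely stated, so the applied values are always logged); an explicit
user-supplied assay-failure drop list (assay failure is not computable);
exclusion of genes with any Normal-pool MSP level ≥ `positive_level`
(default 1, i.e. any methylation) or a blood flag; and prioritization of
genes methylated in ≥ 5 cancer pools ("more than four"), ranked by count
with alphabetical tie-break. Every gene ends with exactly one verdict and a
reason, so retained ∪ excluded reconstructs each stage's input.

## QMSP quantification

`M-index = 10,000 × 2^(Cp_ref − Cp_gene)` with COL2A as the reference gene.
A reaction with reference Cp > 36 cycles is a *detection failure*: the
sample is flagged invalid and excluded listwise from all downstream
statistics, never encoded as zero. The cutoff applies to the reference gene
only — a late target Cp is a legitimate low-methylation measurement. The
index halves exactly per extra target cycle and anchors at 10,000 when the
two Cp values are equal. No floor or clipping is applied to small indexes.

## Marker evaluation

Grades are ordered Normal < CIN1 < CIN2 < CIN3/CIS < SCC (CIS and CIN3 parse
into the combined category). Three standard dichotomizations split the
spectrum at its upper segment: CIN2+/CIN1−, CIN3+/CIN2−, SCC/SCC−.

- **Trend tests:** Kruskal–Wallis across grades (midranks, tie correction,
  chi-square p; all-tied data returns H = 0, p = 1) and pairwise
  Mann–Whitney against Normal. The Mann–Whitney p is exact by full
  enumeration when both arms have ≤ 8 observations (valid under ties,
  two-sided tail `P(|U − mn/2| ≥ |U_obs − mn/2|)`), otherwise the tie- and
  continuity-corrected normal approximation.
- **Medians:** seeded percentile-bootstrap 95% CIs (2000 resamples); fewer
  than 3 values yields a flagged point estimate without a CI.
- **AUC:** the Mann–Whitney identity (pairwise comparisons with ties counted
  one half) with a DeLong-variance normal CI truncated to [0, 1]. The AUC is
  invariant under strictly increasing transforms of the index.
- **Cutoff:** Youden's J maximized over observed values under the ≥ positive
  rule, ties broken toward higher specificity and then the larger cutoff
  (deterministic); a fixed-cutoff mode reproduces published operating
  points. CI methods (DeLong, Wilson, percentile bootstrap) are package
  choices, echoed in every report, since published tables rarely state
  theirs.
- **Power:** the two-sided two-proportion z-test power at the observed
  positivity rates and arm sizes — pooled variance under the null, unpooled
  under the alternative, normal approximation. Degenerate identical-extreme
  rates are reported as undefined. "Accuracy" is reported both as
  (TP+TN)/n at the cutoff and, separately, as the AUC, since the two usages
  coexist in this literature.

Significance is reported at two-sided p < 0.01; α = 0.05 two-sided drives
the power computation and all confidence levels.

## Synthetic-data generators

**Tiling arrays.** Probes tile each chromosome at fixed spacing (default
100 bp, 50 bp probes). Promoters (default 1 kb) are placed evenly and a
configurable fraction per group is planted as hypermethylated: probes whose
midpoint falls inside a planted promoter get a mean log2-ratio shift of
`effect_size` (default 1.5) over baseline noise with standard deviation 0.5.
Noise can be smoothed with a variance-preserving moving average over
`fragment_smoothing_bp` (default 400 bp), emulating the spatial correlation
induced by 300–500 bp sonication fragments; 0 gives i.i.d. probes. Truth
(group, region, gene) is returned separately from the data.

**QMSP cohorts.** Per grade, M-indexes are log-normal around a configured
median — a deliberate minimal model matching the positive support and wide
CIs of published per-grade medians; dispersion defaults to 1.5 on the
natural-log scale. Defaults use the published grade medians
(0.01/0.06/0.19/1.71/31.95) and evaluable cohort sizes (156/55/31/46/39).
Reference Cp is N(30, 1); the target Cp is set to
`Cp_ref − log2(M/10,000)` so quantification inverts the generator exactly
(round-trip relative error < 1e−9). A `failure_rate` fraction of samples
(default 0.01, matching the ~3/330 attrition between enrolled and evaluable
grade counts in the motivating study design) draws reference Cp above 36.
`true_auc` gives the generator's closed-form AUC for any dichotomization:
each arm is a log-normal mixture weighted by cohort sizes and
`P(LN(μ₁,σ₁) > LN(μ₀,σ₀)) = Φ((μ₁−μ₀)/√(σ₁²+σ₀²))`.

**What the generators do not emulate:** probe GC/affinity effects, dye bias,
batch structure, linkage between a patient's array and QMSP measurements,
non-log-normal heavy tails, HPV status, or pooling effects (MSP pools are
treated as single samples — whether pooled DNA averages methylation linearly
is not modeled). Passing tests therefore demonstrate correctness and
calibration of the *computations* under the stated model, not clinical
performance on real cohorts; with the default dispersion the generator's
grade separation is cleaner (CIN3+ AUC ≈ 0.98 in the closed form) than
published clinical AUCs.

## Calibration and recovery checks (problem sizes)

The statistical checks run at desk scale: null calibration uses 20 seeded
i.i.d. arrays of 10,000 probes (the mean per-probe rate of score ≥ 2.0 must
respect the 10⁻² exact-p guarantee up to Monte-Carlo slack); planted
recovery uses 20 arrays of 6,000 probes with 75 planted 2 kb promoters each
(effect 1.5, noise 0.5, i.i.d. noise so the permutation null is exact),
requiring ≥ 95% region recovery and ≤ 1% spurious calls; AUC recovery uses
the published cohort sizes and a ×10 replica with a tolerance shrinking as
1/√n; type-I calibration uses 10,000 null simulations. Planted fractions in
the recovery setting are substantial (half of 150 promoters), reflecting
CpG-island promoter arrays where enriched fractions are large; the planted
probes thicken the background's right tail, which is what keeps spurious
null calls rare at cutoff 2.0.

## Known limitations

- The vendor software's exact windowed-KS recipe is unpublished; the
  window-membership rule (midpoint ± width/2), global background, and the
  small-window exact-p regime boundary are package choices, all configurable
  and logged.
- Region construction (merge gap, minimum probe support) is likewise a
  package choice mirroring the window width.
- The asymptotic KS bound is conservative; scores from windows larger than
  the exact limit understate significance slightly.
- The DeLong CI is asymptotic and can be degenerate when the AUC is exactly
  1; the bootstrap median CI undercovers below ~20 observations.
- Detection-failure exclusion assumes failures are independent of grade and
  methylation level; informative failure is not modeled.
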