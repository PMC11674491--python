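# Methods

This note documents the models and procedures implemented in `exocargo`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make every output
deterministic.

## Vesicle size summaries

PDI = (σ/d)² is computed exactly as written. When raw diameters are given,
σ is the *sample* standard deviation (n−1 denominator) and d the arithmetic
mean; the population/sample choice is not dictated by the formula itself, so
the sample convention was fixed and is recorded here. PDI is scale-invariant
and non-negative. Whether an instrument's reported PDI uses intensity- or
volume-weighted moments is outside this package's scope; the printed formula
is applied to whatever distribution is supplied. Zeta-potential values are
pass-through: no electrophoretic-mobility model is applied.

## Composite protein-abundance score

Inputs are per-(protein, replicate) rows of Score (identification
confidence), Coverage (percent of sequence covered) and Area (integrated
peak area). Conventions:

- **Replicate filter.** A protein is kept when detected in at least
  `min_replicates` (default 2) *distinct* replicates. Counting is per
  distinct replicate index, never per row.
- **Aggregation.** Metrics are averaged over the replicates in which the
  protein was detected (arithmetic mean); `aggregate="sum"` is available.
  Mean was chosen because it does not penalize a protein for missing one
  replicate beyond the filter itself.
- **Normalization scope.** Min-max normalization is computed over the
  *filtered* set, per metric, independently. A constant column maps to all
  zeros (any constant preserves the induced order; 0 is used and logged).
- **Weights.** Defaults 0.2 / 0.2 / 0.6 (Score / Coverage / Area); they must
  sum to 1 within 1e-12. Area dominates as the closest abundance proxy.
- **Ties.** Equal combined scores order lexicographically by accession, so
  output ranks are a deterministic permutation of 1..n.

Upstream identification machinery (search engines, FDR control at PSM level)
is out of scope; the pipeline starts at the exported protein table.

## Small-RNA processing

- **Adapter trimming** truncates at the leftmost occurrence (at or after
  position 1) of the longest adapter prefix of ≥ 6 nt, matched exactly.
  Longer prefixes win over more-leftward shorter ones. No indel-tolerant
  alignment: at desk scale the exact rule is transparent and idempotent.
- **Quality exclusion.** "Below Q25" is interpreted as *mean* read Phred
  quality < 25 → read excluded (a per-base-minimum mode is available).
  Qualities are Phred+33. Malformed quality strings drop the record and are
  counted, never fatal.
- **Length filter** keeps reads strictly longer than 17 nt (≥ 18).
- **Collapsing** merges identical sequences; multiplicities always sum to the
  input read count.
- **Quantification** assigns a collapsed read to the unique mature reference
  it equals or occurs within (sliding-window Hamming ≤ `max_mismatches`,
  default 0). Reads matching several references are discarded as ambiguous
  and tallied, never fractionally assigned — counts stay integer and
  deterministic. Precursor/hairpin mapping, novel-miRNA discovery and isomiR
  resolution are out of scope.
- **Consistency filter** keeps miRNAs with a positive count in *every*
  sample of the group (default: all samples).
- **Ranking** is by row mean of counts-per-million, descending, ties
  lexicographic. CPM was chosen as the normalization for ranking because it
  is the simplest depth correction; size-factor normalization (below) is
  available as an alternative.

## Differential secretion (two-group NB Wald)

The design is exactly two groups (A vs B, labels in lexicographic order with
A the numerator), which admits a closed-form fit instead of IRLS:

1. **Size factors** s_j: median over all-positive rows of counts divided by
   the row geometric mean, rescaled so the factors' geometric mean is
   exactly 1. Fails with a clear message (suggesting a pseudo-count) when no
   row is all-positive.
2. **Dispersion.** On normalized counts q = K/s, each group contributes the
   method-of-moments estimate α_g = (s²_g − m_g)/m_g²; the two are pooled
   with (n_g − 1) weights and floored at 1e-8.
3. **Trend moderation.** With three samples per group a per-miRNA variance
   estimate has ~4 degrees of freedom; plugging it into a normal Wald
   reference is strongly anticonservative (simulation at 5000 null miRNAs,
   α = 0.1, n = 3 vs 3 gives ~12% of raw p < 0.05 at the nominal 5% level).
   A parametric trend α(μ) = a₀ + a₁/μ is therefore fitted across miRNAs by
   least squares on the informative estimates, and the pipeline default
   (`dispersion_mode="trend"`) uses the trend value — full borrowing of
   strength across features, the same rationale as DESeq2's dispersion
   shrinkage, reduced to its transparent core. The same simulation under
   trend moderation gives ~5% type-I error. `fit_dispersion_trend` exposes a
   `prior_weight` to blend per-miRNA and trend values; `per_mirna` mode
   remains available for many-sample designs.
4. **Wald test.** log2FC = log₂(q̄_A/q̄_B); a pseudo-count of 0.5 replaces a
   zero group mean (occurrences logged). The delta-method variance of a
   group's log₂ mean is Var = (1/(n²ln²2)) Σ_j (1/(q̄ s_j) + α); the Wald
   statistic log2FC/SE is referred to N(0, 1), two-sided. No log2FC
   shrinkage, independent filtering, or outlier (Cook's distance) handling —
   deliberate divergences from DESeq2, which this package does not attempt
   to reproduce in full.
5. **BH adjustment** uses the statsmodels step-up implementation; tests hold
   it to exact agreement with an independent brute-force step-up.
6. **Classification** uses strict inequalities: up if log2FC > 1 and
   padj < 0.05, down if log2FC < −1 and padj < 0.05. "Fold change ≥ 2" and
   "log2FC > 1" differ only at the boundary; the strict form is implemented.
   The `high_tier` flag marks log2FC > 5 regardless of class.

PCA QC runs on log₂(CPM+1), features centered, with a deterministic sign
convention (largest-magnitude loading positive per component).

## Interactome integration

- Duplicate (miRNA, gene) target edges across source databases merge with
  evidence-set union before filtering.
- **Evidence filter:** an edge survives when any of its evidence labels
  contains a validated-method keyword (case-insensitive substring; defaults:
  reporter assay, luciferase, western blot, immunoblot, qrt-pcr).
- **Confidence filter:** PPI edges with score ≥ 0.7 are kept — the boundary
  is inclusive ("minimum score 0.7" read as attainable).
- **Shell expansion:** caps (10 first-shell, 5 second-shell) apply globally,
  not per seed; candidates are ranked by the maximum confidence of an edge
  into the current set, ties lexicographic. The upstream database UI does
  not publish its internal selection rule, so this explicit deterministic
  rule is used.
- **DAG identification** is a literal set intersection: genes with ≥ 1
  surviving target edge from the profiled miRNAs and ≥ 1 surviving PPI edge
  to a profiled exosomal protein. An unfiltered "raw" mode
  (`prefiltered=True` on pre-processed tables) supports sensitivity
  analysis. The protein-as-target statistic reports the profiled proteins
  that themselves appear as validated target genes, as "x out of y".
- **Layers** partition the node set; a profiled protein that is also a
  target and/or DAG-qualified stays in the `exosomal_protein` layer with
  `is_target` / `is_dag_qualified` attributes recording its dual roles
  rather than guessing a single placement.
- Multiplicity grouping buckets target genes by distinct targeting miRNAs
  (1 / 2 / ≥3); duplicate edges count once. Disease ranking is descending by
  publication count, ties lexicographic, absent genes scoring 0.
- GraphML export is lossless for layers and edge types; SIF and TSV edge
  lists are also written, with deterministic node ordering.

## Enrichment

One-sided upper-tail hypergeometric p-values, P(X ≥ k), via
`scipy.stats.hypergeom.sf` — all analyses here are enrichment-directional.
The −log₁₀(p) > 2 convention equals p < 0.01; a "log10(p) > 2" reading is
impossible for p ≤ 1 and is therefore interpreted as the negated logarithm.
Query genes outside the universe are dropped with a logged count.

## Synthetic-data generator

Every generator is a pure function of its configuration; distinct generators
draw from independent RNG streams derived from the one seed, so regenerating
any artifact is byte-identical.

Defaults and what they emulate:

- **Protein table:** 240 candidate proteins, detection probability 0.35 per
  replicate across 3 replicates — the expected ≥ 2-replicate filtrate is
  ~68 proteins, matching the scale of a small exosome proteomics study.
  Latent metrics: Score log-normal(ln 200, 0.8), Coverage 100·Beta(2, 3),
  Area log-normal(ln 1e7, 2) (heavy-tailed). Metric values are identical
  across detected replicates by default (`metric_noise_sd = 0`), which makes
  the truth ranking exact; replicate noise is switchable.
- **Counts:** 72 miRNAs (the scale of a consistent exosomal miRNA
  complement), 3 samples per group, baseline means 10^U(1, 3.5) expected
  counts, NB dispersion 0.1, library-size multipliers log-normal(0, 0.15) —
  mild but non-trivial, so size-factor estimation is testable. Planted
  effects default to log2FC magnitude 3 on 25% of miRNAs (signs split
  evenly); exact up/down counts (`n_up`, `n_down`) override the fraction,
  and planted effects are drawn at baselines ≥ 200 expected counts so power
  is governed by the effect, not by counting noise.
- **Reads:** mature sequence + 3′ adapter, random-base padding to 50 nt,
  substitution errors at `error_rate` (default 1e-3; set 0 for exact
  round-trips), and two quality tiers straddling Q25 (pass: per-base 36–40;
  fail, at `low_quality_frac`: 8–20). Mature references are 18–26 nt,
  avoid the adapter's 6-nt prefix and are pairwise non-substring, so
  error-free reads trim and map unambiguously — this is what makes exact
  count recovery a meaningful contract rather than a coincidence.
- **Interactome:** exactly `n_true_dags` genes receive both a validated
  target edge and a ≥ 0.7-confidence PPI edge to a profiled protein; decoys
  exercise each filter (target-only, PPI-only, non-validated evidence,
  sub-threshold confidence at ≤ 0.695, kept clear of the 0.7 boundary).
  About half the profiled proteins also appear as validated targets but
  receive no qualifying PPI edge of their own, so the planted DAG set is
  exactly recoverable. Disease publication counts are Poisson(3) with a
  Poisson(15) boost on planted DAGs.
- **Gene sets:** one set overlaps a designated query at a stated fraction;
  the rest are random draws of 10–30 genes.

What the generator does *not* emulate: realistic human interactome topology
(degree distributions, clustering), sequence-composition biases, ligation
biases of small-RNA library prep, isomiR heterogeneity, correlated
replicate structure, and batch effects. Passing the planted-truth tests
therefore demonstrates the pipeline's internal correctness and calibration
under its stated model, not robustness to every artifact of real libraries.

## Problem sizes used by the verification suite

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
statistical contracts sharp while completing in minutes on one CPU: 1000
random tables (≤ 200 rows) for ranking-oracle equivalence, one full
error-free study (72 miRNAs × 6 samples, ~5×10⁵ reads) for exact count
recovery, 5000 null miRNAs for type-I calibration (accepted band 3–7% at
nominal 5%), ten 2000-miRNA studies with planted 44-up/40-down designs for
power and FDR, 500 random interactomes for DAG brute-force equivalence, and
10⁴ random vectors for BH exactness. The acceptance script reports slightly
smaller Monte-Carlo batches for the oracle-agreement fractions (300 tables,
5 DE seeds, 2000 BH vectors); these are its own reporting sizes, and all
randomness derives from the `--seed` argument.

## Known limitations

- The Wald test's normal reference relies on trend-moderated dispersions;
  with strong per-feature dispersion heterogeneity and very small n, the
  trend can over- or under-disperse individual features (the same trade-off
  any shrinkage estimator makes).
- Quantification is exact-match-oriented; reads from miRNAs absent from the
  reference, or heavily edited reads, land in the unmatched tally.
- The evidence filter is keyword-substring based; unusual evidence
  vocabularies require passing custom keywords.
- Shell expansion and DAG identification operate at gene-symbol granularity;
  protein-accession inputs need a user-supplied mapping.
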