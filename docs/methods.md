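# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make the
pipeline deterministic.

## Normalization

Filtering acts on **raw** counts: a gene is removed iff its arithmetic
mean count is strictly below the threshold (default 10) in *both*
groups. The both-groups rule, rather than a pooled-mean rule, keeps
genes expressed in only one line — exactly the genes a two-breed
contrast is most interested in (e.g. an adipose gene near zero in one
line and in the hundreds in the other). The pooled-mean alternative is
available as `overall-mean-below`.

RPM is count / sample total × 10⁶. The log2 transform adds a
pseudocount of 1 before the logarithm, so zero counts map to exactly 0
log-units and the transform stays monotone; the variance-stabilizing
intent of the log is unaffected by this choice at the expression levels
that survive filtering.

Quantile normalization is the classic rank-mean procedure: the
reference distribution is the per-rank mean of the sorted columns, and
each value is replaced by the reference at its rank. Ties within a
column receive the mean of the reference over the tied rank span (the
common convention), which makes the procedure exactly idempotent — a
property the tests assert to 1e-12. After normalization every sample
has the identical sorted value multiset and identical column mean.

Two practical consequences of normalizing whole transcriptomes are
worth knowing. First, forcing all columns to one distribution induces
a weak negative correlation between genes (a compositional
constraint); a set-level statistic summed over a large fraction of the
genome is therefore slightly conservative under the global null. At
realistic proportions (a ~700-gene set in a ~9,500-gene transcriptome)
the effect is negligible. Second, when a large fraction of the genome
carries true effects, the treated group's cross-gene distribution is
wider than the control's, and quantile normalization compresses it by
roughly baseline_sd / √(baseline_sd² + effect_sd²); between-group log
ratios shrink accordingly. This is the familiar failure mode of
distribution-matching normalization under pervasive change, and it is
visible in the simulator's strongly shifted regimes.

## Differential expression

The per-gene test is the two-sided pooled-variance Student *t* with
n_A + n_B − 2 degrees of freedom; an unequal-variance (Welch) variant
is behind a flag. When both group variances are zero the test
degenerates: equal means give t = 0, p = 1; unequal means give p = 0
with a logged warning, since the pooled formula has no finite answer.

Fold changes are computed from the normalized log2 group means, not
from raw counts: fold = 2^M for M ≥ 0, −2^(−M) otherwise. The signed
convention is a bijection between the reals and (−∞, −1] ∪ [1, ∞), so
no information is lost and a printed fold of −2 always means a halving.

DE calling uses strict inequalities on both criteria (p < α,
|fold| > threshold; defaults 0.05 and 1.3) and applies **no**
multiple-testing correction by default. This is a deliberate,
documented design: the single-gene lists feed set-level statistics
(the binomial skew test), co-expression heatmaps and enrichment tools,
all of which aggregate over many genes, and a per-gene FDR correction
would trade the genome-wide sensitivity those analyses need for
per-gene error control they do not use. Benjamini–Hochberg is
available via `fdr="bh"` for users who want per-gene guarantees.

Under the simulator's null (no planted effects) the caller's empirical
type-I rate at p < 0.05 is calibrated: the acceptance suite measures
it over ~59,000 gene-tests and requires 0.05 ± 0.01.

## Directional gene-set skew

Matching is case-insensitive exact string matching of symbols — no
ortholog mapping; any cross-species conversion belongs upstream.
Each matched gene is classified by its M value: up if M > ε, down if
M < −ε, tied otherwise. ε defaults to 0 (a gene is tied only at
exactly M = 0); real data show a "not changed" category, and ε is the
explicit knob for it. A useful choice is ε ≈ 0.1–0.38 log2 units
(0.38 = log2 1.3, the fold-relevance threshold), which removes the
coin-flip zone where direction is dominated by noise.

The test is exact: with n = n_up + n_down trials and
k = min(n_up, n_down), p = min(1, 2·P[X ≤ k]) for X ~ Binomial(n, ½).
Tail-doubling was chosen over the minimum-likelihood two-sided rule as
the simplest defensible convention; at strongly skewed counts the two
agree. Ties are excluded from n because a tie carries no directional
evidence. A continuity-corrected normal approximation exists behind a
flag for very large sets; the exact test is the default and the tested
path. The test suite verifies exact equality with exhaustive pmf
summation for every split with n ≤ 20.

## Hierarchical clustering of extreme DE genes

The 20 most up- and 20 most down-regulated DE genes (by signed fold,
ties broken by smaller p then gene id) are row-standardized to mean 0,
sd 1 with the population divisor n, then genes and samples are
clustered agglomeratively with Ward linkage on Euclidean distances.
Ward/Euclidean was chosen because the original tool's settings are
unreported; average linkage and correlation distance are selectable.
The tested surface is leaf orders, linkage matrices and the purity of
the two-cluster cut of the sample tree (best-matched agreement with
the true groups), not heatmap pixels; the heatmap image is an optional
matplotlib export.

## qPCR relative quantification

Technical replicates are averaged on the Ct scale (standard practice),
then ΔCt = Ct(target) − Ct(reference) per sample,
ΔΔCt = mean ΔCt(A) − mean ΔCt(B), and relative expression 2^(−ΔΔCt),
reported in the same signed-fold convention. Concordance with RNA-seq
is scored by sign agreement only: a magnitude criterion is not part of
the default because no defensible threshold exists, and on the packaged
20-gene validation panel sign agreement alone reproduces the published
16 concordant / 4 discordant split exactly (the four discordant genes
are precisely the sign flips: PLN, LMOD2, IL23R, ACE). Amplification
-efficiency correction (Pfaffl) is out of scope.

## The synthetic-data generator

`generate_counts` draws, per gene g and sample s:

  count ~ NB(size = dispersion, mean = μ_g · ℓ_s · 2^(e_g · [s ∈ A]))

with μ_g ~ logNormal(baseline_log_mean, baseline_log_sd) (natural-log
parameters), library factor ℓ_s ~ logNormal(0, libsize_log_sd), and
planted log2 effect e_g, nonzero for a `de_fraction` of genes, with
magnitude |N(0, de_log2_effect_sd)| and direction down with probability
`geneset_down_fraction` for designated set members and ½ otherwise.
Defaults emulate the motivating study's design: 6 samples per group,
9,500 expressed genes, baseline_log_mean 6.5 / sd 2.0 (tens of millions
of reads per sample, few genes below the filter), dispersion 15
(between-bird CV ≈ 26%), de_fraction 0.27 (the study called ~27% of
retained genes DE), a 699-gene set with 70% of its true effects down
(447 of the 641 directional set genes pointed down). One top-level seed
expands into fixed named substreams (abundances, library sizes, DE
assignment, set membership, directions, magnitudes, counts, Ct), so
identical configs are bit-identical and one stage's draws never perturb
another's.

`generate_ct_table` derives a replicate-level qPCR panel from the same
truth: target Ct = base_g − e_g·[s ∈ A] + N(0, noise_sd) per reaction,
reference Ct constant across groups plus the same noise, three
replicates per cell, panel = the 20 most extreme planted effects (ten
per direction by default). At zero noise the ΔΔCt pipeline recovers
each planted signed fold exactly, which the tests assert.

What the generator does **not** emulate: read-level artifacts (GC and
length bias, mapping ambiguity), batch effects, correlated gene
modules, and exact expression ties. Passing tests therefore demonstrate
that the statistical machinery is correct under the assumed generative
model, not that the model captures every property of real libraries.

### Study conditions used by the heavier checks

- *Type-I calibration*: generator defaults with de_fraction = 0,
  6,000 genes × 10 seeds (~59,000 null tests) — small enough to run in
  seconds, large enough that the ±0.01 band is ~25 binomial standard
  errors wide.
- *Planted-skew recovery*: a 700-gene set, 65% of true effects down,
  in a low-dispersion (size 150), pervasively shifted (de_fraction 1.0,
  effect sd 1.0) transcriptome of 9,500 genes with a wide baseline
  (log-sd 2.5), direction calls with ε = 0.1. This is the regime of a
  strongly divergent inbred-line contrast in which nearly every set
  member truly moves — the situation the skew test exists to detect
  (real data showed 92% of set members changed directionally). The wide
  baseline keeps the quantile-normalization compression described above
  to a few percent, and the ε band absorbs the remaining coin-flip
  zone; under these conditions the set's estimated down fraction tracks
  the planted truth within ±0.05 in every run and the exact test
  rejects at p < 10⁻⁶ in ≥ 95% of 100 seeds.
- *Cluster separation*: de_fraction 0.3 with effect sd 2.5 and
  dispersion 40, so the 40 selected genes all carry |log2 effect| ≥ 2;
  the two-cluster cut then recovers the 12 samples' groups exactly.

## Determinism and I/O conventions

All tables are tab-separated UTF-8 with a header, no quoting, floats
rendered with ≥ 6 significant digits (`%.10g`); genes are ordered
lexicographically and samples by (group, id), so identical inputs
rewrite byte-identically and run manifests can compare sha256 digests.
Group A is the first group label to appear in the design file — design
order, not alphabetical order, fixes the contrast orientation. Gene
identifiers are treated as opaque symbols, upper-cased only for
matching.

## Known limitations

- The pooled t-test on log2 counts is approximate at very low
  expression; the filter keeps the approximation in its comfortable
  range, but p-values for genes near the filter boundary are the least
  reliable.
- Quantile normalization assumes most genes are unchanged; under
  pervasive asymmetric change it attenuates true log ratios (see
  above). Size-factor methods (TMM/DESeq-style) are deliberately out of
  scope.
- The binomial skew test treats genes as independent; shared regulation
  within a set makes the null optimistic on real data, so the p-value
  should be read as a descriptive index of skew strength rather than a
  literal error rate.
- Exact reproduction of the motivating study's data-dependent totals
  (retained-gene and DE-gene counts, per-gene folds) is impossible
  without its unpublished raw reads; the pipeline instead reproduces
  the fixed-input statistics exactly and the data-dependent behavior
  distributionally on synthetic data.
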