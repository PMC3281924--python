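# Methods

This note documents the models, parameter choices and numerical conventions
behind `seedtx`, and what the synthetic benchmarks do and do not establish.

## Data model and preprocessing

All analysis operates on gene-level log2 intensity matrices.  Probe-level
algorithms (GC-RMA background correction, the MAS5 probe-pair Wilcoxon
detection call) are intentionally out of scope: every downstream computation
consumes normalized gene-level values and Present/Absent labels, so the
package provides the label semantics rather than the probe algebra.
Normalization is quantile normalization (each array mapped onto the row-mean
of sorted columns; ties averaged; idempotent by construction).  Detection is
a threshold rule with two modes:

- `absolute` — Present where the log2 value exceeds a fixed threshold
  (default 6.0);
- `quantile` — Present where the value strictly exceeds that array's q-th
  quantile (default q = 0.30), so a constant array is all-Absent.

A gene is *expressed in a group* only when Present in **all** replicates of
that (tissue, stage, treatment) group, and expressed in a scope (e.g. "the
seed" = all embryo and endosperm groups) when expressed in at least one
group of the scope.  The quantile mode by construction marks the bottom
30% of each array Absent regardless of biology; the pipeline therefore
defaults to the absolute rule, which matches the generator's detection
geometry (expressed baselines 7–13 log2 units, absent genes planted below a
6.0 floor).  Replicate QC reports the Pearson correlation between the two
replicate arrays of each group over all genes.  Low-expression filtering
drops genes Absent in every array (`all-absent`) or with maximum value < 0
(`negative`).

## Moderated differential expression

Two-group contrasts use the ordinary pooled-variance fit
(`estimate = mean(A) − mean(B)`, `d_g = n_A + n_B − 2`,
`v = 1/n_A + 1/n_B`) followed by empirical-Bayes variance moderation: the
scaled inverse-chi-square prior `(d_0, s_0²)` is estimated by moment
matching on `log s_g²` using digamma/trigamma identities, with `d_0` found
by Newton inversion of the trigamma function (tolerance 1e-8).  When the
observed spread of `log s_g²` does not exceed sampling noise the prior is
taken as degenerate (`d_0 = ∞`, `s_0² = mean(s_g²)`), which reduces the
statistic to a pooled z-like form; forcing `d_0 = 0` reduces it to the
ordinary t.  Zero-variance genes receive a variance floor of 1e-8 with a
warning rather than infinite statistics.  The implementation is checked
against Bioconductor limma (`lmFit` + `eBayes`) to ~1e-14 on a shared
fixture.

Decision thresholds follow the study design: predominance at BH q < 0.0005
and linear fold > 2 (interpreted as log2FC > 1 on the log2 matrix, one-sided
in the tissue's favor); time-course at raw ANOVA p < 0.001 (deliberately not
FDR-adjusted; exposed as a config value); cold response at p < 0.05 and
|log2FC| > 1, two-sided, with "up" meaning higher in the treated/later
group.  The predominance reference group is the union of root, leaf,
seedling and ovary samples; the tissue group pools all stages of the tissue.
Time-course direction is the sign of last-stage minus first-stage mean.
BH-FDR is the standard step-up procedure (statsmodels' `fdr_bh` behind the
package surface, verified against a from-definition implementation).
Whether the original fold filter used linear- or log-scale averages is not
stated anywhere authoritative; this package uses log-scale group means
throughout, which is the convention the moderated model estimates.

## Enrichment statistics

Category enrichment uses the 2×2 table {in-set, out-of-set} × {in-term,
out-of-term} over an explicit background, with the closed-form Pearson
chi-square `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, df = 1, **no** Yates
continuity correction (the convention of the era's array pipelines).  Tables
with any expected cell below 5 are flagged (`low_expected`) rather than
silently switched to an exact test.  Only over-representation
(`a/n > K/N`) counts as enrichment; depleted or untested cells carry a `-`
marker in the exported `-log10 p` matrix.  The default background is the
set of genes present in the analyzed matrix after filtering; a whole-genome
background is a caller choice (both are defensible and the original choice
is unrecorded).  TF-family enrichment is the same statistic with the
background restricted to TF genes.

Promoter analysis extracts up to 3000 nt upstream of each gene's translation
start (CDS extent if annotated, else the gene span): plus-strand gene at s →
genomic `[max(1, s−L), s−1]`; minus-strand gene ending at e → reverse
complement of `[e+1, min(contig_end, e+L)]`; truncation only at contig
boundaries, and upstream windows are not clipped at neighboring genes.
IUPAC patterns are scanned on both strands with overlapping occurrences
counted; a genomic `N` matches only pattern letter `N` (conservative
non-match, since an ambiguous base carries no evidence for a specific
degenerate class).  Cis-element enrichment is gene-level by default: the
fraction of genes with ≥1 occurrence in the group versus the universe
(occurrence-count mode is available), chi-square as above, BH across the
library, enriched at q < 0.05.

## Co-expression annotation

TF neighborhoods are the top k = 500 genes by Pearson correlation across the
compendium (after all-absent filtering), ties at the k-th rank broken by
ascending gene id so output is deterministic; self-correlations are
excluded, zero-variance genes dropped with a warning, and negative-PCC
ranking is not used.  Each neighborhood is GO-annotated by chi-square
enrichment against the compendium background with per-TF BH correction;
edges enter the bipartite TF–term network at q < 0.05 (a documented choice —
no threshold is recorded for the original network figures; 0.05 matches the
cis-element rule).  TF nodes carry their predominance class, term nodes
their labels, edges their q-values; export is SIF or GraphML.

## The synthetic generator

`simulate_compendium` mirrors the study layout: embryo at 3/6/9/12 DAF,
endosperm at 3/6/9/16 DAF, root/leaf/seedling/ovary references, two
replicates (24 arrays).  Gene values are
`baseline + planted offsets + Normal(0, σ_g²)` with `σ_g²` drawn from the
scaled inverse-chi-square prior (defaults d_0 = 4, s_0² = 0.05 log2²
units — replicate noise sd ≈ 0.22, typical of good hybridization
replicates).  Defaults: baselines uniform on [7, 13] log2 units; 10% absent
genes at 4.5 ± 0.5 (clipped below the 6.0 detection floor); 5% / 4% / 1.5%
embryo/endosperm/both predominance at +2 log2 (4-fold, a typical planted
effect for tissue-predominant storage and regulatory genes); 2% time-course
genes per seed tissue, half up, half down.  A `heavy_tail_fraction` switch
contaminates the noise with t(3) draws for robustness experiments.

Time-course trajectories are **mean-centered** monotone offsets with a
2.0 log2 step per stage (−3, −1, +1, +3 for four stages).  Centering keeps
time-course genes neutral in the predominance contrast, so the two planted
signal classes stay orthogonal and recovery metrics are unambiguous.  The
step size matters: with two replicates per stage the one-way F has only
(3, 4) degrees of freedom, and a 1.0-step trajectory at this noise level has
roughly 50% power at p < 0.001 — the 2.0 step (an 8-fold swing across
development, common for storage-program genes) is the smallest round value
giving ≥90% recovery, and is declared as the study condition for the
recovery benchmarks.

The cold experiment plants additive log2 effects on the treated arrays of
one stage only (defaults: 150 down, 50 up per stage at ±2 — the early-stage
down-regulation asymmetry), in a 2-stage × treated/control × 2-replicate
(8-array) layout.  `simulate_compendium(cfg, seed, truth=...)` replants an
existing truth with fresh noise, emulating an independent biological
replication (the two-cultivar comparison setting) for trend-concordance
checks.

`simulate_coexpression_collection` builds TF modules over `n_arrays` arrays:
TF profiles are i.i.d. Normal(μ, 1), members are
`baseline + r·(TF − μ) + Normal(0, 1 − r²)` so the expected member–TF PCC is
exactly `r` (default 0.8); all other genes are independent noise.  The size
of the public compendium behind the original network is unrecorded, so
`n_arrays` is a free parameter (60 in the benchmarks).

`simulate_promoter_sequences` plants exactly one concrete realization of an
IUPAC element at a uniform position and strand in target promoters
(group genes with probability `target_fraction_in_group`, others with
`background_fraction`) over i.i.d. background at a stated GC;
`simulate_promoters` additionally emits a one-contig-per-gene genome FASTA +
GFF3 whose extraction round-trips byte-identically.  The bundled motif
library is a small synthetic PLACE-style set, **not** the curated database.
Its decoy patterns deliberately share no sequence core with the GCN4-like
element on either strand: a decoy that overlaps the planted element (e.g. a
W-box TTGACY against the TGACTCA reverse complement) becomes genuinely
co-planted at insertion junctions, which would make specificity benchmarks
measure library redundancy instead of statistical false positives.

### What the benchmarks do not show

The generator is Normal on the log2 scale with independent genes (outside
planted modules), no batch or spatial artifacts, no probe-level effects, and
planted effects of a single magnitude.  Passing recovery benchmarks
therefore demonstrates correctness of the statistics and decision rules
under the assumed model, not robustness to the correlation structure,
outliers and annotation noise of real hybridization compendia.  Two
limitations deserve emphasis:

- **Finite-compendium network precision.**  With i.i.d. TF profiles, chance
  TF–TF correlation scales as 1/√n_arrays — and so does the top-k PCC
  cutoff, so the rate at which one module's members leak into another TF's
  neighborhood is nearly independent of compendium size.  At q < 0.05 this
  yields on the order of 1–3 extra (TF, term) edges per 5 modules beyond
  the planted ones, at 60 and at 300 arrays alike.  Planted edges are
  nevertheless always recovered and are each TF's strongest annotation;
  consumers of the exported network should rank edges by q rather than
  treat the 0.05 cut as a precision guarantee.
- **Chi-square in sparse tables.**  With genome-scale backgrounds the
  expected in-neighborhood count for a small term is ≪ 5; the Pearson
  statistic is anti-conservative there, which is why such tables carry the
  `low_expected` flag and an exact-test fallback is available in the
  enrichment configuration.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state.  Pipeline outputs are written
with a fixed float format (`%.6g`) so identical (config, seed) runs are
byte-identical; the JSON manifest records the config hash, seed, expressed
counts, class counts and estimated hyperparameters.  A failed stage removes
its partial outputs and reports the stage name.  Benchmark problem sizes
(5,000-gene compendium, 40–100 promoter replicates at 800–1000 nt,
2,000-gene/60-array network collection) were chosen so the full validation
suite completes in about a minute on one CPU while keeping every recovery
margin comfortably away from its threshold.
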