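# Methods

This note documents the statistical procedures implemented in `tmex`, the
defaults and their rationale, the synthetic world used for validation, and
the numerical conventions a user should know before trusting a result.

## 1. Quality control and normalization

Cells are removed first — fewer than 200 detected genes (strict `<`) or a
mitochondrial count fraction strictly above 10% — and then genes detected in
fewer than 10 of the surviving cells. The cell-first order matters: gene
detection counts are computed on the surviving cells only. The filter is
idempotent. "Mitochondrial fraction" means the share of a cell's total
counts carried by `MT-`-prefixed genes, the standard convention.

Single-cell normalization is counts-per-10k with ln(1+x):
`lognorm = ln(1 + 1e4 · count / cell_total)`. It is exactly invariant to
per-cell count rescaling. No variance-stabilizing regression is applied;
all downstream single-cell statistics operate on this scale.

Bulk normalization uses median-of-ratios size factors: the per-gene
reference is the geometric mean across samples over genes with no zeros,
and a sample's factor is the median ratio to that reference. Two identical
samples get factors (1, 1); a sample exactly double another gets
(1/√2, √2) — the geometric-mean reference splits the libraries' difference.
Bulk values enter all correlation computations as log₂(x+1).

## 2. Markers and signatures

Marker detection is one-vs-rest per cluster. Genes are pre-filtered by
expressing fraction (`pct_in ≥ 0.10`; "expressing" means lognorm > 0) and by
log₂ fold-change (`≥ 0.5`) before testing, then tested with a two-sided
Wilcoxon rank-sum (normal approximation, tie-corrected, no continuity
correction) and BH-adjusted within each cluster's tested set — adjusting
within cluster matches the one-vs-rest framing, where each cluster's test
family is interpreted separately.

The fold-change convention is
`log2((mean(expm1(lognorm_in)) + 1) / (mean(expm1(lognorm_out)) + 1))`:
means on the de-logged scale with a pseudocount of 1, so it is finite for
silent genes and antisymmetric under swapping the groups.

Signature sets per cell type keep genes with `pct_in` strictly over 0.25
and log₂FC strictly greater than 0.5, ordered by fold-change descending.
The two pct thresholds (10% for testing, 25% for signatures) are deliberate:
testing casts a wide net, signatures demand robust detection.

## 3. Co-occurrence network

The network asks: which cell types rise and fall together across a bulk
cohort? The five steps and their numerical conventions:

1. **Abundance.** Type t's abundance in sample s = mean log₂(x+1) of t's
   signature genes. This is a relative score, not a deconvolved proportion —
   only its variation across samples is used.
2. **Correlation.** Pearson r between each gene's log₂(x+1) bulk profile and
   each abundance row, over samples (≥3 required). Zero-variance genes are
   recorded as r = 0 and flagged undefined; they can never be selected.
3. **Non-self candidates.** A gene is self-expressed for type t if its mean
   lognorm over t's cells is strictly greater than 1 AND its expressing
   fraction in t strictly exceeds 20%. Self-expressed genes are removed so
   that the top-20 list reflects co-occurring partners, not the type's own
   transcripts; the remainder are ranked by signed r (positive
   co-occurrence; `abs_corr` switches to magnitude). The expression
   threshold is evaluated on the lognorm scale, the scale on which
   single-cell means are conventionally reported.
4. **Enrichment.** e(j) = mean lognorm of the candidate genes in type j;
   z = (e − ē)/sd(e) with sample sd (T−1). With ~6–10 types the T−1 choice
   materially changes z, and 1.28 is the usual one-sided 90% normal point
   under this convention. An all-equal e vector yields all-zero z
   (degenerate; nothing passes).
5. **Edges.** Directed hit i→j iff z strictly exceeds 1.28. An undirected
   edge exists if at least one direction hits; when both hit, the weight is
   the maximum of the two scores. Requiring mutual hits is available
   (`mutual_only`) but not the default: a single passing direction is
   treated as evidence of co-occurrence.

Why the null stays quiet: under independent mixing proportions, the genes
that correlate best with type t's estimated abundance are t's own weakly
expressed genes (those below the self-filter thresholds). Their enrichment
concentrates on t itself — and self-edges are never evaluated — so the
z-mass that sampling noise produces is absorbed by the excluded diagonal.
Measured on the default 6-type world this leaves ≈0.25 false edges per run.

Hub ranking sorts types by undirected degree, ties by weighted degree, then
lexically.

## 4. Ligand–receptor permutation test

The test statistic for (donor A, acceptor B, pair L→R) is the mean of two
cluster means, (mean L in A + mean R in B)/2, on the lognorm scale. The
null shuffles cell labels (preserving cluster sizes) and recomputes;
p = #{null ≥ observed}/n_perm with no +1 correction, so exhaustive
enumeration and the estimate coincide exactly on tiny instances (a
`plus_one` flag gives the conservative (k+1)/(n+1) variant). Null cluster
means are computed without re-masking: masking is a property of the
observed labeling.

Genes expressed in under 10% of a cluster's cells are masked there, and a
pair with a masked ligand or receptor is *skipped* for that cluster pair —
never scored as zero — so absent combinations cannot dilute the result
table. Significance applies the secreted filter: p < 0.05 (strict) and
ligand annotated secreted. The interaction-strength matrix counts
significant pairs per ordered cluster pair; its symmetrization (S + Sᵀ)
summarizes undirected interaction load.

The display statistic √(mean(L·R)+1) is exactly that — a display value for
dot plots, reported per row but never used for inference. It is computed
over a resampled cell pairing of length max(|A|,|B|) (a full cross product
is quadratic), deterministic given the run seed. Computing it over cluster
means instead of cells is the one-flag alternative; the per-cell resampling
default is documented here rather than asserted as canonical.

## 5. Gene-set scoring

**Module score** (binned-control): genes are cut into 24 equal-size bins of
average expression; each gene-set gene contributes 100 control genes drawn
with replacement from its bin; score = mean(set) − mean(controls) per cell.
The defaults (24, 100) follow the original binned-control scoring method.
Adding a constant to the expression matrix cancels exactly. Scores on
exchangeable data center at 0.

**ssGSEA**: genes ranked by expression descending, ties broken by gene id
for determinism. With rank values N..1 (top gene = N), the score is
Σᵢ (Pin(i) − Pout(i)) where Pin is the running sum of in-set rank-weights
(weight = rank^0.25, normalized) and Pout the out-set ECDF; the sum is
divided by N to bound the scale. The score depends only on ranks, hence is
invariant to any strictly monotone transform of expression. It can be
computed per cell or per cluster pseudobulk (mean lognorm profile); both
are exposed because heatmap-style summaries typically use the pseudobulk
route.

Across-group z-scoring uses sample sd per gene set; zero-variance rows are
returned as zeros.

## 6. Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` (product-limit estimator; hypergeometric variance with
simultaneous-event pooling). The package fixes the stratification
conventions:

- **Median split**: High iff value strictly above the median; ties at the
  median go Low, so "High" is always strictly above.
- **Pair stratification** (default `mean-z`): per-sample score = mean of the
  z-scored log₂(x+1) expression of ligand and receptor, then median split.
  The alternative reading — High = above median on *both* genes — is the
  `both-high` rule; it produces a smaller High group and is offered because
  the two-gene construction is genuinely ambiguous. With ligand = receptor
  both rules reduce to single-gene stratification.

## 7. The synthetic world

The generator's defaults describe the validation cohort: 6 cell types ×
80 cells, 1500 genes, 20 markers per type at fold 4, negative-binomial
counts with shared dispersion 0.3 (variance = μ + 0.3μ²), 200 bulk samples,
20% multiplicative lognormal bulk noise, first 5% of genes `MT-`-prefixed.
Cohort shape (≈10 or fewer annotated types, a few hundred cells per type,
≈200 bulk samples) mirrors a typical tumor single-cell atlas paired with a
TCGA-scale cohort; fold 4 is a strong but realistic marker contrast.

Mixing proportions are logistic-normal: latent Gaussian logits with the
requested correlation matrix (nearest-PSD repaired by eigenvalue clipping
at 1e-8; min eigenvalue below −0.3 is an error), scaled by
`proportion_sigma = 0.4`, softmaxed per sample. Two attenuation effects are
inherent and documented rather than corrected: softmax saturation (grows
with sigma) and simplex closure, which caps the realizable correlation
(≈0.70 for a latent 0.8 among 6 types) and induces r = −1/(T−1) between
independent types. At sigma 0.4 a latent 0.8 realizes near 0.65.

Planted ligand–receptor pairs take their ligand from the donor type's
marker genes and receptor from the acceptor's, so specificity is inherited
from the marker structure; decoys use uniformly expressed non-marker genes.
Survival times are exponential with log-hazard = β · standardized mean
log₂(x+1) expression of the effect genes, censored by an independent
Uniform(0, 30) at baseline hazard 0.1 (≈35% censoring).

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, per-gene dispersion, zero-inflation beyond NB, non-proportional
hazards, and informative censoring. A green planted-recovery test therefore
establishes algorithmic correctness and calibration under a clean mixture
model — not robustness to real-data artifacts.

## 8. Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; every stochastic stage is byte-reproducible.
- Sorting that affects output order uses stable sorts with documented tie
  breaks (gene id, lexical type id).
- Strict inequalities at every quoted threshold (25%, 0.5, 1.28, 0.05, the
  self-filter's 1.0 and 20%) are asserted by boundary tests.
- Genes missing from one side of a bulk/single-cell comparison are dropped
  with a warning and counted, never silently zero-filled.
- `find_markers` skips clusters with fewer than 3 cells (warning); Wilcoxon
  needs at least that to be meaningful.

## 9. Known limitations

- Abundance scores are signature means, not deconvolved fractions; types
  with correlated signatures (shared lineages) can share candidates.
- The co-occurrence procedure assumes bulk expression is approximately a
  linear mixture on the measurement scale; strong compositional effects at
  small type counts induce the negative closure correlation noted above.
- Multi-subunit receptor complexes are not modeled; the database schema is
  simple pairs.
- The permutation p-value has resolution 1/n_perm; with the default plain
  proportion it can be exactly 0. Use `plus_one` when p-values feed
  multiple-testing procedures that assume p > 0.
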