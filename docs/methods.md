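# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## The allelic model of XCI

At a heterozygous X-linked SNP in a female cell, RNA-seq reads support
either the allele on the active X (Xa) or the one on the inactive X
(Xi). Under complete inactivation the Xi allele should contribute
nothing; in practice a small fraction of reads is miscalled to the wrong
allele (alignment error, sequencing error, residual mapping bias). All
escape calling in this package therefore tests the Xi read fraction
against an empirical error bound rather than against zero:

- **p₀ = 0.025** — the upper bound on the allele-miscall fraction,
  chosen from the worst observed miscall rate at *XIST* sites in fully
  skewed samples (where the expressed allele is unambiguous). A gene
  escapes only if its Xi fraction is significantly above this bound:
  one-sided exact binomial, `P(X ≥ xi | n = xi + xa, p₀)`.
- **q < 0.01** — FDR control (Benjamini–Hochberg) applied within each
  tissue (bulk) or each sample (single cell) separately.
- **Jeffreys intervals** — Beta(k + ½, n − k + ½) central quantiles on
  every reported Xi fraction, with lo = 0 at k = 0 and hi = 1 at k = n.

The Xi/Xa expression *ratio* at a gene is `xi/xa`; fractions convert via
`r = f/(1 − f)`. Escape genes typically sit near r ≈ 0.33, PAR1 genes
near r ≈ 0.80 (incomplete even where escape is obligatory), which is why
PAR1 genes come out male-biased at the population level: females express
(1 + r) X-doses against the male X + Y = 2.

## Skewed-donor calling (`skewed_donor`)

A donor whose tissues all inactivate the same X makes Xi reads directly
observable in bulk data. The stages follow the allelic model above plus:

- **Site selection** — one site per gene: the site with ≥ 8 reads
  (">7") in the most tissues; ties break to the smallest genomic
  coordinate, so the choice is invariant to input order.
- **Xi orientation** — the allele with the lower pooled expression
  across tissues is Xi; at *XIST* (expressed exclusively *from* Xi) the
  higher one. Genes with exactly balanced pooled counts are unresolved
  and excluded. Note this folding rule biases measured Xi fractions
  downward for genes near balance (a winner's-curse effect); ratios for
  nearly balanced regions such as PAR1 are better estimated from
  haplotype-phased data (see below).
- **Cross-tissue classification** — a gene is incompletely inactivated
  only if its cross-tissue evidence survives a *gene-level* FDR: the
  per-tissue binomial p-values are combined with Simes' rule and
  BH-corrected across genes at q < 0.01. Per-tissue q-values control the
  error rate per observation; a union over 16 tissues would otherwise
  accumulate false gene-level calls to above the nominal level (we
  measured ~1.1–1.3% without the gate, ~0 with it, at unchanged
  sensitivity ≥ 0.99 for genes with Xi fraction ≥ 0.1). Among non-full
  genes: exactly one significant tissue among ≥ 2 *powered* tissues →
  `incomplete_single_context`; otherwise significant-tissue Xi fractions
  within a max/min ratio H = 3 → `incomplete_shared`, else
  `incomplete_heterogeneous`. A tissue is "powered" when its coverage
  gives ≥ 80% power to detect Xi fraction 0.10 at the 0.01 level — this
  makes "escapes in one tissue only" a falsifiable claim rather than a
  coverage artifact.
- **Skew estimation** — read-weighted major-allele fraction across
  inactive-catalogued nonPAR sites, folded to [0.5, 1] (parental
  labelling is discarded; unphased donors carry none). Requires ≥ 5
  informative sites, otherwise undefined with a reason.

## Single-cell calling (`single_cell`)

Each female cell expresses X genes almost exclusively from its one
active X, so the expressed alleles at fully inactivated sites are
perfectly correlated across cells sharing the same active parental X.

- **Biallelic detection** (per cell-site, ≥ 8 reads): minor fraction
  > 0.05 AND nominally (p < 0.05) above p₀. A gene is biallelic with
  ≥ 2 such observations across cells. Sites biallelic in > 10% of their
  assessed cells, plus all PAR1 sites, are excluded from phasing — these
  are exactly the sites where both haplotypes express.
- **Trio-phased assignment** — majority vote of a cell's expressed
  alleles against the maternal/paternal haplotypes; exact 50:50 support
  or no informative sites → uninformative.
- **Reference-free phasing** — cells are nodes of an agreement graph
  (+1 matching / −1 opposite majority allele at shared non-excluded
  sites); the sign of the leading eigenvector of the agreement matrix
  seeds the bipartition, refined by alternating between the population-1
  consensus haplotype (population 2 expresses the complement at every
  heterozygous site) and per-cell reassignment until a fixpoint. Cells
  with < 80% agreement with their population's haplotype are demoted to
  uninformative (doublet/contamination guard). Output is deterministic
  given a seed (used only for degenerate ties) and invariant, up to the
  global P1/P2 swap, to cell order. Exclusions apply to partition
  *estimation* only; once cells are assigned, every site is phased from
  its population majority so that escape and PAR1 genes can still be
  aggregated. The phase of those excluded sites is itself low-confidence
  (both haplotypes express), which is why phasing accuracy is stated
  over non-excluded sites.
- **Aggregation and calling** — per cell, reads on the cell's active
  haplotype count toward Xa, the rest toward Xi; sums go per site then
  per gene. *XIST* is re-anchored so its dominant allele maps to Xi.
  Genes need ≥ 5 contributing cells and ≥ 8 aggregate reads to be
  assayed (below that they are `not_assayed`, which is distinct from
  inactive); escape is the same binomial-vs-p₀ test with per-sample FDR.
  Aggregating across cells makes the calls robust to per-cell allelic
  dropout, which would otherwise turn escape genes into false negatives.

## Sex-bias statistics (`sex_bias`)

The differential-expression fit is deliberately pluggable: any table of
per-gene per-tissue signed effects and q-values works. The built-in
backend is OLS of log2(expression + 1) on sex plus supplied covariates,
with expression filters (median > 0.1, > 10 samples above 1) applied
per tissue — the bespoke content is downstream of the fit. Downstream:

- per-tissue, per-category proportions of sex-biased genes (q < 0.01);
  categories with zero assessed genes give NaN, never 0;
- paired two-sided exact Wilcoxon between categories across tissues;
- a per-gene *direction* (majority over significant tissues, falling
  back to majority over expressed tissues when none is significant) fed
  into a two-sided exact binomial against 0.5; tied genes are excluded;
- direction concordance = fraction of expressed tissues sharing the
  majority direction (exact ties score 0.5; genes in < 5 tissues are
  omitted), with "escape-like" flags for non-escape-catalogued genes at
  concordance > 0.9 plus significance somewhere;
- the X+Y re-test, which replaces an X homolog's expression with the
  X + Y pair sum — male Y expression can cancel or flip an apparent
  female bias.

## PAR1 X/Y dosage (`par_xy`) and chromatin (`chromatin`)

In males every trio-phased PAR1 heterozygous site separates reads by
chromosome (maternal allele = X, paternal = Y); gene-level sums are
tested two-sided against 0.5 with a Jeffreys CI on the X fraction.
Recombination between an assayed site and the sex-determining region
would break the maternal-equals-X assumption and is out of model.

Chromatin-state coverage (genes × 15 states, rows ≈ 1) is compared
between escape and inactive genes by one-sided Wilcoxon rank-sum per
state and direction. Because both gene sets share one chromosome,
significance is calibrated by label permutation: shuffle the
escape/inactive labels preserving set sizes, recompute all 30 one-sided
p-values per shuffle (the statistic *is* the p-value, smaller = more
extreme), with Bonferroni correction at 0.05/30. Whether to
Bonferroni-correct the rank-sum p or the permutation p is ambiguous in
principle, so both flags are emitted. Inside the permutation loop the
rank-sum p uses a tie- and continuity-corrected normal approximation
with per-column ranks cached (they are label-independent); the reported
observed p-values come from the same statistic so the comparison is
like-with-like.

## Statistical primitives (`stats_core`)

- Two-sided binomial p-values use the minimum-likelihood convention (sum
  of outcome probabilities ≤ the observed one), which equals
  tail-doubling at p₀ = 0.5.
- The exact Wilcoxon signed-rank null is enumerated by dynamic
  programming over doubled midranks (exact with ties) for n ≤ 30, with
  a tie- and continuity-corrected normal approximation above.
- Monte-Carlo permutation p-values use the add-one estimator
  (1 + hits)/(1 + shuffles), which never returns 0; an exhaustive mode
  enumerates all distinct relabelings and returns the exact conditional
  p. Seeded RNG is mandatory for all resampling.
- Storey q-values (pi0 from a lambda grid 0.05…0.95 with cubic-spline
  smoothing) are available; BH is the default because it is
  deterministic and conservative, so borderline calls can differ
  slightly from a qvalue-package analysis.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure the analysis assumes,
with defaults set to the emulated designs: 23% of nonPAR genes escaping
(5.8 points of all genes escaping in exactly one tissue), per-gene Xi
fractions drawn from a Beta re-parameterized by the mean Xi/Xa ratio
(0.33 nonPAR, 0.80 PAR1; concentration 15 gives the wide gene-to-gene
spread seen in real data), a 2.5% allele miscall rate matching p₀, 16
donor tissues, 15 PAR1 genes (the number assessed in the emulated
sex-bias analysis), truncated-Poisson(2) heterozygous sites per gene (to
exercise site→gene collapse), negative-binomial read depths (mean 100×
bulk / 30× per cell-site, overdispersed), per-allele dropout in single
cells (default 0.5), and *XIST* expressed from Xi only. Ground truth is
always written alongside the data and never read by any calling stage.

What the generators do **not** emulate: reference-alignment bias,
position-correlated escape (real escape genes cluster, e.g. around
PAR1/Xp), cell-type or tissue covariance structure, doublets or
contamination, and the realistic power landscape of population DE — the
simulated sex-bias effects are clean enough that nearly all escape genes
reach significance, where the real analysis detected ~74%. Passing
tests therefore validate the *inference machinery* (error control,
orientation, phasing, aggregation) under the assumed generative model,
not performance on real GTEx-like data.

## Problem sizes and numerical choices

Test and acceptance runs use 300–500 genes × 16 tissues (bulk) and
120–200 cells × 50–300 sites (single cell), sizes at which every rate
being checked (FPR ≤ 1%, sensitivity ≥ 0.9, phasing ≥ 99%) has adequate
resolution while a full run stays in seconds. Degenerate inputs are
defined throughout: zero-coverage observations are skipped, exactly
balanced orientations are unresolved rather than arbitrarily broken,
single-class permutations and all-zero difference vectors raise, and
empty tables round-trip as empty tables. All tie-breaks (site selection,
consensus haplotypes) are documented and deterministic.

## Known limitations

- The cross-tissue classifier is a deterministic heuristic, not a
  hierarchical Bayesian model; it does not share information across
  genes and its `incomplete_shared` / `incomplete_heterogeneous` split
  depends on the configurable ratio H.
- The minor-allele orientation rule underestimates Xi fractions near
  balance (PAR1); use phased data for ratio estimates there.
- The skew estimator is a documented stand-in: it summarizes
  major-allele fractions at inactive-catalogued sites and does not model
  cell-lineage sampling variance.
- The DE backend is OLS without precision weights or surrogate
  variables; supply externally computed DE summaries for real studies.
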