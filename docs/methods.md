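# Methods

This note records the statistical model, the conventions chosen where
the analysis design was genuinely open, and what the synthetic data can
and cannot demonstrate.

## Coordinates and formats

All internal coordinates are 0-based with half-open intervals. GFF3
(1-based, inclusive) is converted at the I/O boundary: a '+' gene's TSS
is `start − 1`, a '−' gene's is `end − 1`. Cytosine reports follow the
Bismark cytosine-report shape — per-position methylated/unmethylated
*call counts*, never pre-computed rates — with 1-based positions
converted on read. Zero-coverage rows are retained so coverage can be
distinguished from absence.

## Expression model

FPKM is the unit throughout: `count / ((L/10³)(N/10⁶))` with gene length
L (bp) and library size N (column sum unless mapped-read totals are
supplied). Counting is per gene, not per transcript; isoform-level
quantification is out of scope.

*Fold change.* `fc_expr = (mean FPKM_tol + ε)/(mean FPKM_ctl + ε)` with
pseudocount ε = `pseudo_fpkm` (default 10⁻⁶ FPKM). The floor exists so
genes undetected in one group get large finite fold changes rather than
divisions by zero. Classification (up at ≥ 2.0, down at ≤ 0.5, both
inclusive) is made on the *exact* mean ratio, with the convention
x/0 = ∞: the pseudocount perturbs the ratio just below the threshold for
an exactly two-fold gene, and the inclusive boundary is part of the
decision rule, so the floor is kept out of the comparison. Genes with
zero counts in every sample are classed `undetected` and excluded from
all classification denominators.

*Significance.* A two-sided Fisher's exact test on the pooled 2×2 table
[[gene reads, all other reads] per group]. No per-replicate dispersion
model is fitted; pooling is the simplest construction that yields a
per-gene exact p on count data. This is a deliberate fidelity choice,
not a recommendation: with biological overdispersion between replicates
the pooled test is anti-conservative, which is why the null-calibration
test runs at near-Poisson dispersion and why a Benjamini–Hochberg
adjusted column is available behind the `bh_adjust` flag (off by
default; raw p is what the selection rules consume).

The two-sided p sums the hypergeometric probabilities of every table
with the observed margins whose probability does not exceed the observed
one, with a relative tie slack of 10⁻⁷. It is implemented directly over
the support with log-gamma arithmetic (vectorised, stable for window
tables with ~10⁶ calls); tests cross-check it against exact
integer-combinatorics enumeration (all tables with total ≤ 40) and
against `scipy.stats.fisher_exact`.

*CV.* Sample standard deviation (n−1) over the mean of the tolerized
replicate FPKM values, undefined (NaN) at mean 0. Computed over the
tolerized group only: that convention is what makes the recurring
printed value for genes detected in one of three replicates equal
√3 ≈ 1.732 exactly, independent of the magnitude.

## Methylome model

*Context.* CpG / CHG / CHH (H = A, C, T), read 5′→3′ on the cytosine's
own strand; on '−' the downstream bases are the complemented forward
bases at decreasing coordinates. CpG needs only the first downstream
base; CHG/CHH need both; an N or chromosome-edge lookup that is actually
required makes the context `undefined` and the position is dropped from
the enumerated cytosine table.

*Window.* `[max(0, tss − w), tss)` on '+', `[tss + 1, tss + 1 + w)` on
'−' (clipped at the chromosome end), with w = 10 000 bp. The TSS base is
excluded; both strands' cytosines contribute (dropping one would
silently halve the call totals).

*Group statistics.* Rates use pooled counts (Σ M over cytosines and
replicates / Σ T), not means of per-replicate rates — robust at low
coverage. The count fold change instead compares the group means of
per-replicate methylated counts, so an exactly unchanged gene reports
1.000; 0/0 gives NaN, which never satisfies the ≤-style selection rules.
A gene is `uncovered` when either group has zero calls in its window,
and uncovered genes are excluded from classification denominators and
selection cascades (counted in the selection report).

*Context summary.* A cytosine counts as "methylated" when it has at
least one methylated call; shares are relative to the per-sample total
of methylated cytosines, and the CpG rate pools calls over all CpG
records.

## Selection rules

Demethylated list: fc_rate ≤ 0.5 ∧ p_meth < 0.05 ∧ fc_count ≤ 1.0 ∧
control methylated-call sum ≥ 3. Joint candidates: fc_expr ≥ 2.0 ∧
p_expr < 0.05 ∧ fc_rate ≤ 0.9 ∧ fc_count ≤ 1.0. All comparisons
inclusive; significance means raw p < α = 0.05. The top-expressed
highlight restricts to genes that are both significant and classed up,
then flags (a) the top 10 by fold change (ties broken by descending fold
then lexicographic gene id), (b) genes detected in every tolerized
replicate, (c) curated transcription regulators.

Enrichment uses the plain one-sided hypergeometric tail and fold
enrichment (k/n)/(K/N); no EASE-style k−1 correction is applied, a
noted divergence from DAVID-family servers.

## Summary percentages

Class percentages are reported to two decimals by largest-remainder
(Hamilton) apportionment over {up, down, unchanged}, so the printed
parts always sum to exactly 100.00 and "altered" equals up + down with
no rounding drift. Independent rounding can disagree with apportionment
by one unit in the last place for individual classes.

## Synthetic data: what it models

Counts are negative binomial with mean `nb_mean` (default 100) and shape
`nb_dispersion` (default 10, i.e. variance = μ + μ²/10 — moderate
biological overdispersion). Coverage is Poisson (default mean 10, a
typical whole-genome bisulfite depth); methylated calls are binomial at
the context rate — CpG 0.75, CHG/CHH 0.01 by default, matching the
mammalian somatic pattern in which essentially all methylation is CpG
and CpG sites are ~75% methylated. The genome is i.i.d. nucleotides at
GC 0.42 (mouse-like); with these defaults roughly three quarters of
"methylated cytosines" fall in CpG context, mirroring the structure of
real bisulfite libraries. Candidate genes couple an `expr_effect`-fold
expression increase (default 8, optionally with control counts forced to
zero and/or detection in a single tolerized replicate) with a
`demeth_effect` scaling of promoter-window CpG methylation (default
0.4) in tolerized samples only. Three replicates per group is the
default design. Genes are laid out in equal slots so every promoter
window is complete and pairwise disjoint; one seed drives all stages
through per-stage child generators, making datasets byte-reproducible.

Not modelled: read-level noise and bisulfite conversion error, CpG
islands and genomic sequence composition structure (the i.i.d. genome
under-represents real CpG depletion), library-size imbalance beyond what
the spiked effects induce, SNPs, and between-replicate methylation
variability (calls are binomial at a shared rate). Passing recovery
tests therefore demonstrate that the pipeline's statistics and decision
rules behave as designed under their own assumptions — not that the
cascade has any particular sensitivity or specificity on real tissue
data, where overdispersion and composition effects are stronger.

One composition effect is worth knowing about: strongly spiked genes
inflate the tolerized library sizes, so null genes' FPKM fold changes
sit below 1 and some are classed "down". This is inherent to
FPKM-ratio analysis without compositional normalisation (no TMM/DESeq
size factors, which are out of scope) and is visible in the synthetic
runs' class percentages.

## Problem sizes

The recovery design used by the tests and the acceptance script is 200
genes on a 2.4 Mb chromosome (≈1 M cytosines), 3 vs 3 replicates, 10
spiked candidates, 50× coverage — large enough that window tests are
well powered and binomial noise is small, small enough to run in tens of
seconds. Unit fixtures use 12–20 genes on 0.1–0.3 Mb.
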