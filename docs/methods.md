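# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `bindweave`, in the order the pipeline runs.

## Coordinates and interval algebra

All coordinates are 0-based half-open (`[start, end)`), BED-native.
Adjacent intervals never overlap; a 1-based annotation source must be
converted at the reader boundary. Consensus sites are formed by pooling
every assay-A interval that overlaps an assay-B interval by at least
`min_overlap` bases (default 1) together with the B intervals it touches,
then merging the pool into maximal ≥ 1 bp-overlap clusters. This makes
the cluster count symmetric in the argument order and the output sorted
and non-overlapping; self-intersection of a set reduces to its plain
merge. Peaks are assigned to genomic feature classes by their midpoint;
classes are multi-label (a promoter window can contain a TSS window), so
per-class fractions may sum to more than 1. Feature-class defaults:
promoter = TSS −1,000..+200 (strand-aware), TSS = ± 100 bp; exon/intron
require an exon BED, an enhancer class requires a user BED. The
per-class background is the class territory's share of genome bases, and
significance is a two-sided binomial test of the observed midpoint count
against that share.

Gene proximity ("within 1 kb") is measured as the gap to the *gene body*
(distance 0 on overlap), not to the TSS alone: promoter-proximal binding
is then automatically within range, and the choice is monotone in the
window. This is one of several places where the underlying convention is
genuinely open; the distance mode is a documented parameter rather than a
hidden constant.

## Motifs

Built-in motifs are IUPAC consensus patterns: RARE half site `RGKTCA`,
GATA `WGATAR`, and the DR5 composite (two same-strand RARE halves with
exactly 5 intervening bases). Scanning reports every hit on both strands
in plus-strand coordinates with no greedy suppression; `N` never matches.
A PWM mode (log-odds against a uniform background, hit when the window
reaches a configurable fraction — default 0.8 — of the maximum attainable
score) is provided for motifs that a hard consensus represents poorly;
consensus mode is exactly testable against regex expansion and is the
default everywhere. DR5 hits are reported at the start of the upstream
half site in the motif's own orientation, which on the minus strand is
the plus-coordinate `pair_start + 11`.

Heterotypic spacing is the absolute start-to-start distance from each
a-hit to its nearest same-chromosome b-hit, strand-agnostic; a midpoint
mode exists. In restricted mode only hits inside the supplied regions
count.

## Permutation tests

Two exchangeable nulls, both deterministic under a fixed seed:

* **Region enrichment** — each query interval is relocated independently
  and uniformly over all placements that fit entirely inside the universe
  (whole chromosomes, or a supplied region set such as accessible
  chromatin), length preserved; relocated intervals may overlap each
  other. The statistic is the number of query intervals with ≥ 1 bp
  reference overlap; one-sided for enrichment.
* **Spacing** — b-hit positions are redrawn uniformly with per-chromosome
  counts preserved; the statistic is the mean nearest-neighbor distance;
  one-sided for *smaller than null*.

Empirical p-values use the plus-one estimator
`(1 + #{null at least as extreme}) / (1 + N)`, which never reports 0.
Because the overlap count is integer-valued, the estimator is exactly
uniform only when the statistic has enough distinct values; with very
small query/reference sets ties make it conservative. The calibration
experiments therefore use 50 query × 60 reference intervals (200/300 bp)
on a 100-kb chromosome and 30 × 40 motif hits, where the measured type-I
rate at α = 0.05 sits within [0.03, 0.07] over 1,000 repetitions.
Permutations are vectorized per chromosome in numpy; a `--threads` flag
is accepted for interface compatibility but results are independent of
it by construction.

## Exact tests and FDR

Fisher's exact test is implemented by explicit enumeration of the
conditional hypergeometric distribution: the two-sided p sums the point
probabilities not exceeding the observed table's (with a 1 + 1e-7 tie
guard); the odds ratio is the sample `ad/bc` with `inf` for `bc = 0,
ad > 0` and 1 when both products vanish. Benjamini–Hochberg is the
classical step-up, input order preserved, `q ≥ p` elementwise.

## Differential count test

A self-contained two-group test shared by the expression, accessibility,
and spectral-count layers:

1. effective library sizes: raw column totals rescaled by
   median-of-ratios factors (per-sample median ratio to the per-feature
   geometric-mean reference over zero-free features, geometric mean of
   factors fixed to 1, overall scale anchored to the raw totals). Raw
   totals are biased when strong effects are asymmetric between groups —
   in the planted benchmark this shifted every null log2FC by about
   −0.2 and inflated false calls in one direction — and the robust sizes
   remove that bias. With fewer than 10 zero-free features the raw
   totals are used unchanged;
2. CPM normalization; `log2FC` of group-mean CPMs with a 0.5 pseudocount
   (finite for zero counts);
3. an exact conditional binomial p per feature: given the pooled raw
   count, the group-a share is binomial with success probability equal
   to group a's share of the effective library; all-zero features get
   `p = 1`, `log2FC = 0`;
4. BH q over all features.

**Stated limitation:** the conditional binomial null is exact for
Poisson-distributed counts. Under negative-binomial overdispersion the
p-values are anti-conservative (at dispersion 0.1 the q-values alone do
not control FDR). The classification rules always pair the FDR cut with
a fold-change cut, and in the planted benchmarks it is that pair — not
the q-value alone — that delivers empirical FDR ≤ 0.10 at overdispersed
settings. The q-only recovery guarantee is demonstrated in the
near-Poisson regime (dispersion 0.001). The test is a plug-in point: a
proper NB test can be substituted per feature without touching the
classification layer.

## Classification rules

Fold-change thresholds are linear-scale and inclusive (`FC ≥ 2` ⇔
`|log2FC| ≥ 1`): expression and interactome use FDR ≤ 0.05 with FC ≥ 2,
accessibility uses FDR ≤ 0.05 with FC ≥ 1.5. Binding dependence requires
a DEG call in *both* the WT-vs-empty and WT-vs-C88A contrasts, in the
same direction by default (a direction-agnostic mode is available; the
directional reading is the biologically coherent one for a
binding-dead-control design). Direct targets are binding-dependent DEGs
with a consensus site within the 1-kb proximity window of the gene body.
Genotype-specific accessibility is deliberately asymmetric: presence in
exactly one genotype's peak list plus FC ≥ 1.5 on normalized counts,
with no FDR gate. Interactome calls pool both TurboID orientations
(N- and C-terminal fusions) against the ligase-only control, upward
only; the binding-dependent subset additionally passes the same
thresholds upward against the C88A construct, so the subset chain
`binding-dependent ⊆ interactors` holds by construction. Fold-change
summaries (e.g. the CRISPR indel frequency ratio) are ratios of means
reported to two decimals, round-half-even.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every decision rule can be scored against a
planted truth without any external accession.

* **Genome**: i.i.d. nucleotides at a configured GC fraction (default
  0.41, mouse-like). Motif instances are concrete draws from the IUPAC
  consensus, planted without overlap (20-bp safety gap); heterotypic
  pairs are planted same-strand at a fixed or Normal-distributed
  start-to-start spacing. Background windows matching any planted
  consensus (either strand) are rejection-resampled until none remain,
  so planted occurrences are the only exact matches — clean ground truth
  is preferred over sequence realism here.
* **Peak sets**: a fraction *f* of A-peaks receives a ≥ 1 bp-overlapping
  B-peak; all other placements are kept disjoint within and across sets
  so that the planted consensus count is exactly the number of
  overlapping pairs. Out-of-bounds placements are clipped with a logged
  warning. Optionally a fraction of A-peaks is centered on planted
  motifs.
* **Counts**: negative binomial with `Var = μ + φμ²`; per-feature
  baselines are log-normal around the configured mean. Three designs:
  two-group; empty/WT/C88A (the binding-dependent planted subset loses
  its effect in C88A, the rest keep it); and
  control/WT_N/WT_C/C88A spectral counts (planted up-regulated proteins
  are the true interactors; the binding-dependent subset stays at
  control level in C88A).
* **Streams**: every artifact draws from its own RNG stream derived from
  the master seed by a fixed offset, so adding an artifact never
  perturbs earlier draws; identical config + seed gives byte-identical
  FASTA/BED/TSV output.

Not emulated: read-level data (FASTQ), fragment-length/Tn5 insertion
structure, single-cell UMI sampling, mappability or GC bias, correlated
replicates, and motif-like background sequence. Passing the planted
benchmarks therefore demonstrates the correctness and calibration of the
decision rules under the stated noise model, not robustness to the
artifacts of real sequencing data.

## Shipped end-to-end configuration

The demo run (`examples/demo_config.yaml`, also `demo_config()` in
code) is scaled to desk size: a 3-Mb, 3-chromosome genome; 400 planted
RARE–GATA pairs at Normal(85, 20) bp spacing plus 200 single plants of
each motif; 400 peaks per assay (mean width 250 bp) at overlap fraction
0.5 with 40% of A-peaks anchored on plants; expression at NB mean 100,
dispersion 0.1, 2,000 genes × 4 replicates per group, 10% planted at
|log2FC| = 2 (twice the DEG threshold), half binding-dependent;
accessibility at NB mean 200, dispersion 0.02 (bulk-replicate
variability), planted |log2FC| = log2 3 (twice the FC-1.5 threshold);
spectral counts at NB mean 30, dispersion 0.1, 800 proteins. Genes are
300 bp; half of the planted binding-dependent genes are anchored within
the 1-kb window of a consensus site (these are the true direct targets)
and all other genes are kept > 1.2 kb away. Open chromatin covers 90% of
true consensus sites in both genotypes, which both mirrors the
biology-motivated expectation that binding occurs in already-accessible
regions and gives the enrichment permutation a planted signal. The full
run completes in well under a minute on one CPU; permutation stages use
199 permutations by default (999 for standalone tests).

## Numerical conventions

Empirical p-values are never 0; Fisher ties use a relative 1e-7 guard;
BH uses a stable mergesort; fold-change reporting rounds half-even to
two decimals; degenerate inputs (empty peak sets, all-zero features,
empty hit lists, zero library sizes, infeasible plant packing) raise
explicit errors or documented sentinel values as listed in the
docstrings. The JSON run summary is written atomically, contains every
parameter and seed needed to reproduce it, and is byte-identical across
reruns of the same config and seed.
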