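# bindweave

Multi-omic integration of transcription-factor binding, chromatin
accessibility, gene expression, and proximity-labeling interactome data —
with a synthetic-data generator that plants a known ground truth under
every analysis stage.

## The problem

Fusion oncoproteins such as PML::RARA reprogram hematopoietic progenitors
by binding DNA and recruiting cofactors (GATA2 among them). Dissecting
that mechanism requires stitching together several assay layers:

- **binding sites** from two orthogonal assays (ChIP-seq and CUT&RUN),
  kept only where both agree;
- **motif structure** at those sites — retinoic-acid response element
  (RARE) half sites `RGKTCA`, direct repeats with a 5-bp spacer (DR5),
  and GATA motifs `WGATAR` — including how closely heterotypic motif
  pairs sit together;
- **chromatin accessibility** (ATAC-seq) differences between genotypes;
- **differential expression** with a DNA-binding-dead point-mutant (C88A)
  contrast that separates binding-dependent from binding-independent
  regulation;
- **protein interactions** from TurboID spectral counts, again with a
  C88A contrast.

`bindweave` implements the full decision logic of such a study as a
tested, deterministic pipeline. Because the real datasets require
controlled-access accessions and upstream alignment, the package ships a
first-class synthetic generator: genomes with planted motif instances and
controlled pair spacing, dual-assay peak sets with a controlled overlap
fraction, and negative-binomial count tables with planted differential
and binding-dependent features — so every downstream call can be scored
against a known truth.

## The statistics at the core

- **Consensus sites**: clusters of intervals from assay A overlapping
  assay B by ≥ 1 bp (half-open coordinates), merged per cluster.
- **Region-set enrichment**: one-sided permutation test; each query
  interval is relocated (length preserved) uniformly within a universe;
  `p = (1 + #{null ≥ obs}) / (1 + N)`.
- **Motif spacing**: mean nearest-neighbor start-to-start distance
  between two motif classes, with a permutation null that repositions
  the second class uniformly (per-chromosome counts preserved); one-sided
  for *closer than chance*.
- **Differential counts**: CPM on median-of-ratios effective library
  sizes; `log2FC = log2((m_a + 0.5)/(m_b + 0.5))`; exact conditional
  binomial p (group-a pooled count vs pooled total at the library-share
  null); Benjamini–Hochberg q.
- **Classification rules**: DEG/accessibility/interactome classes at
  `FDR ≤ 0.05` and fold-change ≥ 2 (expression, interactome) or ≥ 1.5
  (accessibility); *binding-dependent* = same-direction DEG in both the
  WT-vs-empty and WT-vs-C88A contrasts; *direct target* =
  binding-dependent DEG with a consensus site within 1 kb of the gene
  body; Fisher's exact test (full hypergeometric enumeration) for
  proximity × direction association.

## Worked example

```python
import bindweave as bw

cfg = bw.SynthConfig(
    genome_length=500_000, chrom_count=2, seed=7,
    motif_plants=[bw.MotifPlant("RARE_half", 100, pair_with="GATA", spacing=(85.0, 20.0))],
    peak_params=bw.PeakParams(n_peaks=200, mean_width=150, overlap_fraction=0.5),
    count_params=bw.CountParams(n_features=1000, n_samples=4, nb_mean=100,
                                nb_dispersion=0.1, effect_log2fc=2.0,
                                planted_fraction=0.1, binding_fraction=0.5,
                                design="binding"),
)
genome, truth = bw.make_genome(cfg)
chip, cutrun, truth = bw.make_peak_sets(cfg, truth)
sites = bw.intersect_consensus(chip, cutrun)
print(f"consensus sites: {len(sites)} (planted: {len(truth.true_consensus_intervals)})")

rare = [h for c, s in genome.items() for h in bw.scan(s, bw.RARE_HALF, chrom=c)]
gata = [h for c, s in genome.items() for h in bw.scan(s, bw.GATA, chrom=c)]
spacing = bw.heterotypic_spacing(rare, gata)
perm = bw.spacing_perm(rare, gata, {c: len(s) for c, s in genome.items()},
                       n_perm=999, seed=7)
print(f"mean RARE-half to GATA spacing: {spacing.mean_spacing:.1f} bp "
      f"(null mean {perm.null_samples.mean():.0f} bp, p = {perm.empirical_p:.3g})")

counts, expr_truth = bw.make_count_table(cfg)
th = bw.Thresholds()
wt_vs_empty = bw.classify_deg(
    bw.differential_count_test(counts.frame, counts.samples("WT"), counts.samples("empty")), th)
wt_vs_c88a = bw.classify_deg(
    bw.differential_count_test(counts.frame, counts.samples("WT"), counts.samples("C88A")), th)
bd = bw.binding_dependence(wt_vs_empty, wt_vs_c88a, th)
n_up = (wt_vs_empty.deg_class == "up").sum()
n_down = (wt_vs_empty.deg_class == "down").sum()
print(f"DEGs: {n_up + n_down} ({n_up} up, {n_down} down); "
      f"binding-dependent: {int(bd.sum())} "
      f"(planted: {len(expr_truth.true_binding_dependent_features)})")
```

prints

```
consensus sites: 100 (planted: 100)
mean RARE-half to GATA spacing: 84.7 bp (null mean 2483 bp, p = 0.001)
DEGs: 104 (52 up, 52 down); binding-dependent: 51 (planted: 50)
```

All 100 planted dual-assay peak pairs are recovered as consensus
clusters; the planted ~85-bp RARE–GATA spacing is recovered against a
~2.5-kb random-placement null; and the 100 planted differential genes
(50 of them binding-dependent) come back with one borderline false call.

## Command line

```sh
bindweave run-all --config examples/demo_config.yaml --out myrun
bindweave consensus --a chip.bed --b cutrun.bed --out sites.bed
bindweave enrich --query sites.bed --reference atac.bed --chrom-sizes chrom.sizes --n-perm 999 --seed 1
```

`run-all` executes synth → consensus → motifs → accessibility →
permutations → expression/targets → interactome and writes a
machine-readable `run_summary.json` (all counts, recovery metrics,
parameters and seeds). Exit codes: 0 success, 2 validation failure,
1 runtime failure.

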