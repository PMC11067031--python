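outdir: bindweave_run
seed: 0
n_perm: 199
thresholds:
  deg_fdr: 0.05
  deg_fc: 2.0
  atac_fdr: 0.05
  atac_fc: 1.5
  interactome_fdr: 0.05
  interactome_fc: 2.0
  proximity: 1000
scheme:
  promoter_upstream: 1000
  promoter_downstream: 200
  tss_halfwidth: 100
synthetic:
  genome_length: 3000000
  chrom_count: 3
  gc_fraction: 0.41
  motif_plants:
  - motif: RARE_half
    count: 400
    pair_with: GATA
    spacing:
    - 85.0
    - 20.0
  - motif: RARE_half
    count: 200
    pair_with: null
    spacing: null
  - motif: GATA
    count: 200
    pair_with: null
    spacing: null
  peak_params:
    n_peaks: 400
    mean_width: 250
    overlap_fraction: 0.5
    motif_anchor_fraction: 0.4
  count_params:
    n_features: 2000
    n_samples: 4
    nb_mean: 100.0
    nb_dispersion: 0.1
    effect_log2fc: 2.0
    planted_fraction: 0.1
    binding_fraction: 0.5
    design: binding
  seed: 0
atac_overlap_fraction: 0.8
atac_effect_log2fc: 1.584962500721156
atac_planted_fraction: 0.1
atac_nb_mean: 200.0
atac_dispersion: 0.02
atac_cover_fraction: 0.9
specific_planted_fraction: 0.3
interactome:
  n_features: 800
  n_samples: 4
  nb_mean: 30.0
  nb_dispersion: 0.1
  effect_log2fc: 2.0
  planted_fraction: 0.1
  binding_fraction: 0.5
  design: interactome
gene_length: 300
inputs: {}
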