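# Demo configuration for `methtriad all --config examples/demo.yaml`.
# Every key shown here carries its default value; omit any section to use
# the defaults unchanged. CLI flags (--seed, --outdir) override the file.
seed: 1
outdir: results

simulate:
  n_genes: 150
  gene_length_range: [2000, 6000]
  cpg_density: 0.02          # CpG sites per bp
  intergenic_gap: 1000
  n_gain: 20                 # genes with planted 5mC gain
  n_loss: 20                 # genes with planted 5mC loss
  delta: 0.2                 # planted gene-body 5mC shift
  log2fc_mag: 1.0            # |log2 fold-change| of coupled genes
  depth_mean: 30.0           # sequencing depth, negative binomial
  depth_dispersion: 5.0
  eps_bs: 0.0                # BS non-conversion error
  eps_ox: 0.0                # oxBS non-conversion error
  e_mab: 0.0164              # MAB-seq non-conversion inefficiency
  n_replicates: 1
  n_per_group: 5             # expression samples per group
  nb_dispersion: 0.1
  lib_size: 1000000.0
  coupling: {gain: up, loss: down}

call:
  min_depth: 10
  e: 0.0164                  # binomial null rate for 5fC/caC calling
  alpha: 0.01                # per-site p threshold
  fdr: 0.01                  # BH q threshold
  mask_bed: null             # optional variant-mask BED

aggregate:
  bin_size: 1000
  min_sites: 3               # sites per gene body per group

express:
  fc_threshold: 1.5
  p_threshold: 0.05
  expression_min: 1.0
  method: builtin            # or `external` with external_table
  external_table: null

integrate:
  modification: 5mC

validate:
  concordance_rho: 0.57      # simulated cohort sign-agreement rate
  magnitude_noise: 0.25
  validation_deltas: null    # optional external cohort delta TSV
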