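# Example cuephylo pipeline configuration.
# With no `inputs` section the pipeline simulates its own study first
# (tree, growth curves, genome features) and records the ground truth.
output_dir: cuephylo_run

simulate:
  n_isolates: 10
  substrates: [glucose, pyruvate]
  temperatures: [15.0, 25.0]
  n_replicates: 3
  tree_seed: 11
  trait_seed: 12
  growth_seed: 13
  genome_seed: 14
  n_kos: 150
  n_causal: 3

# To analyse real data instead, point at existing files and drop `simulate`:
# inputs:
#   growth_csv: data/growth_curves.csv        # isolate,substrate,temperature_c,replicate,time_h,od600,co2_ppm
#   tree: data/isolates.nwk
#   features_tsv: data/ko_counts.tsv          # taxa x KO counts + genome_size column

constants:
  biomass_per_od: 130.0   # ug C per OD600 unit per ml culture
  culture_ml: 10.0
  headspace_ml: 25.0

cue:
  min_points: 3
  max_points: 10
  respiration_method: cumulative   # or: interval
  alpha: 0.05
  min_replicates: 2

q10:
  n_boot: 1000
  boot_seed: 21

phylosig:
  n_perm: 999
  perm_seed: 31
  bm_ci: false
  n_sim: 500

markers:
  alpha: 0.05
  min_prevalence: 4
  explore_fraction: 0.65
  residual_seed: 41
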