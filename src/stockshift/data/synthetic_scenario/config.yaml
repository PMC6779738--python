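# Run configuration for the packaged synthetic scenario (seed 20160101).
# Inputs are resolved relative to this file; outputs go to output_dir.
seed: 20160101
output_dir: out
inputs:
  observations: observations.csv
  baselines: baselines.csv
  panel: panel.fasta
  nest_series: nests.csv
  demography: demography.csv
partitions:
  early_years: [2006, 2007]
  late_years: [2015, 2016]
  scl_cutoffs: [75.0, 50.0]
  year_range: [2005, 2017]
popgen:
  n_permutations: 200
msa:
  n_iter: 1500
  burn_in: 750
  n_chains: 3
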