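# Demo pipeline configuration: laptop-scale simulate -> ... -> select run.
#   markertrait run --config examples/demo_config.yaml --out pipeline_out
seed: 1
sim:
  n_species: 3
  pops_per_species: 3
  families_per_pop: 3
  offspring_per_family: 6
  n_loci: 600
thresholds:
  call_rate: 0.80
  maf: 0.05
  fdr: 0.05
  mlmm_steps: 10
  train_fraction: 0.60
  selection_k: 10
  n_pcs: 5
traits: [BS2010, BB2011, H2013, I2013]
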