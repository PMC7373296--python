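# Demonstration study: 39 cases / 41 controls, 250 proteins, one batch.
# Signal: an eight-protein linear signature (alternating direction,
# |log-odds| 0.5 per standardized log10 unit) plus one U-shaped protein
# (beta2 = 1.5) -- the generator's default effect set.
# Panel iterations are reduced from the 1000-iteration default to keep the
# demonstration run in the minutes range.
seed: 20200721
output: results/pipeline

cohort:
  n_cases: 39
  n_controls: 41
  n_proteins: 250
  default_effects: true
  detection_quantile: 0.10
  mcar_rate: 0.02

preprocess:
  missingness_threshold: 0.5
  local_regression_normalize: false

scan:
  alpha: 0.05
  strata: [all, sr_ibs_cases, non_sr_ibs_cases, females_only]

panel:
  top_k: 20
  iterations: 150
  split: 0.8
  contrasts: [all, sr_ibs_cases, non_sr_ibs_cases]
  n_trees: 300
  boost_rounds: 150
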