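# Desk-scale analysis configuration: a 12-subject cohort (6 young, 6 older)
# for the DCM arm; the behavioral arm runs at the full 14/16 cohort sizes
# inside 02_behavior.py.
data_dir: data
results_dir: results
cohort:
  n_young: 6
  n_older: 6
  master_seed: 2026
bms:
  seed: 2026
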