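# Full default run, written out explicitly.  Any subset of keys may be given.

# target density over (CO, TPR): a measured two-column CSV, or the surrogate
target_file: null        # e.g. data/normotensive_pairs.csv with header "co,tpr"
surrogate_n: 1000

# Metropolis calibration
restarts: 15             # independent chains from the best fit
n_burn: 20               # iterations discarded per chain
n_keep: 20               # retained states per chain (restarts x n_keep patients)

# hemorrhage protocol
rate: 37.5               # mL/min of extracellular fluid removed
duration: 20.0           # minutes of drain
horizon: 40.0            # minutes observed
threshold: 15.0          # mmHg of MAP fall separating the outcomes

# classification
n_trials: 100            # random-split SVM accuracy trials
test_size: 75            # held-out patients per split
mer_repeats: 37          # rubric searches on independent splits
cost_threshold: 0.01     # held-out accuracy gain required per added feature
beam: 50                 # candidate sets kept per search stage

# output
write_series: false      # per-patient hemorrhage time series as CSVs
parameter_file: null     # YAML/JSON of model coefficients (defaults otherwise)
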