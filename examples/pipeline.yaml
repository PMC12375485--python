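# Full-pipeline demo: simulate a default synthetic cohort and run every stage.
out_dir: demo_out
seed: 42
# simulate:              # SimulationConfig overrides, e.g.:
#   richness_benign: 5000
#   richness_malignant: 1500
# preprocess:            # PreprocessConfig overrides, e.g.:
#   downsample_depth: auto-min
# input_dir: my_cohort/  # read an existing cohort instead of simulating
# metadata: my_cohort/metadata.csv
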