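# Frequency 2AFC with machine-teaching trial selection.
# Run:  trialteacher simulate --config examples/configs/2afc_teacher.yaml \
#         --seed 1 --out scratch/run_2afc
preset: 2afc
policy: machine_teaching
budget: 3000
student:
  initial_weights: {bias: 2.0, S1: -2.0}
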