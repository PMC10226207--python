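# Two synthetic survey waves, full pipeline:
#   ineqdecomp full --config examples/two_waves.yml --out scratch/report
waves:
  - label: baseline
    synthetic: baseline
    n: 4000
    seed: 20160211
  - label: followup
    synthetic: followup
    n: 4000
    seed: 20160212
options:
  weighted: true
  ame: derivative
  rounding: 4
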