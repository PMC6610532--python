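data:
  n_classes: 2
  n_samples: 40
network:
  n_gc: 200
protocol:
  metric: euclid
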