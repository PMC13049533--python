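{
  "variant": "tiny",
  "max_steps": 300,
  "base_lr": 0.001,
  "batch_size": 2
}
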