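circumference: 40.0
objects:
- center: 20.0
  height: 0.75
  width: 3.0
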