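{
  "n_mentions": 93,
  "n_positive": 88,
  "n_dropped_unlabelable": 0
}
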