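{
  "ranks": {
    "-5": 1, "-4": 2, "-3": 3, "-2": 5, "-1": 6,
    "0": 8,
    "1": 6, "2": 5, "3": 3, "4": 2, "5": 1
  }
}
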