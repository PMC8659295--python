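{
 "units": "uM",
 "species": {
  "sub": 0.0
 },
 "reactions": {
  "output": {
   "input": "sub",
   "KA": 1.0,
   "n": 1,
   "tau": 1.0
  }
 }
}
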