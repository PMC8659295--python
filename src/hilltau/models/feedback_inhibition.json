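{
 "units": "uM",
 "species": {
  "input": 0.0
 },
 "reactions": {
  "fb": {
   "input": "output",
   "KA": 1.0,
   "tau": 10.0
  },
  "output": {
   "input": "input",
   "ligand": "fb",
   "inhibit": true,
   "KA": 0.5,
   "n": 2,
   "tau": 2.0,
   "tau2": 10.0
  }
 }
}
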