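{
 "units": "uM",
 "species": {
  "pool": 1.0
 },
 "reactions": {
  "kinase": {
   "input": "pool",
   "ligand": "fb",
   "KA": 0.3,
   "n": 6,
   "tau": 2.0,
   "inhibit": true
  },
  "output": {
   "input": "pool",
   "ligand": "kinase",
   "KA": 0.3,
   "n": 6,
   "tau": 2.0
  },
  "fb": {
   "input": "pool",
   "ligand": "output",
   "KA": 0.3,
   "n": 6,
   "tau": 20.0
  }
 }
}
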