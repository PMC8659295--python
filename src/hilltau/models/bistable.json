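{
 "units": "uM",
 "species": {
  "pool": 1.0,
  "stim": 0.13
 },
 "reactions": {
  "fb": {
   "input": "pool",
   "ligand": "output",
   "KA": 0.4,
   "n": 2,
   "tau": 3.0,
   "baseline": 0.1
  },
  "output": {
   "input": "pool",
   "ligand": "fb",
   "KA": 0.9,
   "n": 2,
   "tau": 1.0,
   "modifier": "stim",
   "Kmod": 0.5,
   "Amod": 20.0,
   "Nmod": 2
  }
 }
}
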