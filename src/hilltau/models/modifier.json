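{
 "units": "uM",
 "species": {
  "mol": 1.0,
  "L": 0.0,
  "M": 0.0
 },
 "reactions": {
  "output": {
   "input": "mol",
   "ligand": "L",
   "KA": 0.5,
   "tau": 1.0,
   "modifier": "M",
   "Kmod": 0.5,
   "Amod": 4.0
  }
 }
}
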