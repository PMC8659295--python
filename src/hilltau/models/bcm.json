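{
 "units": "uM",
 "species": {
  "Ca": 0.08,
  "CaMKII": 1.0,
  "CaN": 1.0,
  "AMPAR": 1.0
 },
 "reactions": {
  "kinase": {
   "input": "CaMKII",
   "ligand": "Ca",
   "KA": 2.0,
   "n": 4,
   "tau": 0.5,
   "tau2": 20.0
  },
  "phosphatase": {
   "input": "CaN",
   "ligand": "Ca",
   "KA": 0.1,
   "n": 2,
   "tau": 0.5,
   "tau2": 2.0
  },
  "synAMPAR": {
   "input": "AMPAR",
   "ligand": "phosphatase",
   "inhibit": true,
   "KA": 0.4,
   "n": 2,
   "tau": 2.0,
   "modifier": "kinase",
   "Kmod": 0.3,
   "Amod": 0.01,
   "Nmod": 2
  }
 }
}
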