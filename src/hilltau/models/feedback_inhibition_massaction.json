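{
 "massaction": {
  "species": {
   "input": 0.0,
   "out_i": 1.0,
   "output": 0.0,
   "fb_i": 1.0,
   "fb": 0.0
  },
  "buffered": [
   "input"
  ],
  "enzymes": [
   {
    "enzyme": "input",
    "substrate": "out_i",
    "product": "output",
    "kcat": 2.0,
    "Km": 0.5,
    "Kr": 0.5
   },
   {
    "enzyme": "output",
    "substrate": "fb_i",
    "product": "fb",
    "kcat": 0.4,
    "Km": 0.5,
    "Kr": 0.1
   },
   {
    "enzyme": "fb",
    "substrate": "output",
    "product": "out_i",
    "kcat": 2.0,
    "Km": 0.5,
    "Kr": 0.0
   }
  ]
 }
}
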