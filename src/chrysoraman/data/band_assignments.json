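{
 "schema_version": 1,
 "tolerance": 3.0,
 "entries": [
  {
   "compound": "Cysteine",
   "compound_class": "Amino acids",
   "reference": 512,
   "vibration": "nu(S-S) g-g-g"
  },
  {
   "compound": "Methionine",
   "compound_class": "Amino acids",
   "reference": [
    630,
    670
   ],
   "vibration": "nu(C-S) g"
  },
  {
   "compound": "Methionine",
   "compound_class": "Amino acids",
   "reference": [
    700,
    745
   ],
   "vibration": "nu(C-S) t"
  },
  {
   "compound": "Disordered structure (solvated)",
   "compound_class": "Proteins",
   "reference": 1245,
   "vibration": ""
  },
  {
   "compound": "Lipids/fatty acids",
   "compound_class": "Lipids/fatty acids",
   "reference": [
    800,
    1100
   ],
   "vibration": "nu(C-C)"
  },
  {
   "compound": "Sucrose",
   "compound_class": "Disaccharides",
   "reference": 1462,
   "vibration": "delta(CH2)"
  },
  {
   "compound": "1,8-Cineol",
   "compound_class": "Bicyclic monoterpenes",
   "reference": 652,
   "vibration": "delta(ring)"
  },
  {
   "compound": "Sabinene",
   "compound_class": "Bicyclic monoterpenes",
   "reference": 652,
   "vibration": "delta(ring)"
  },
  {
   "compound": "Crocetin",
   "compound_class": "Tetraterpenes",
   "reference": 1020,
   "vibration": "rho(C-C)"
  },
  {
   "compound": "Chlorophyll a, b",
   "compound_class": "Chlorophyll",
   "reference": 1326,
   "vibration": ""
  },
  {
   "compound": "Chlorophyll a",
   "compound_class": "Chlorophyll",
   "reference": 1549,
   "vibration": ""
  },
  {
   "compound": "Carotenoid",
   "compound_class": "Carotenoid",
   "reference": [
    956,
    957
   ],
   "vibration": ""
  }
 ]
}
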