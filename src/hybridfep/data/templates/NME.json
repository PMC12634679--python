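{
 "name": "NME",
 "formal_charge": 0,
 "atoms": [
  {
   "name": "N",
   "element": "N",
   "type": "N",
   "charge": -0.5
  },
  {
   "name": "H",
   "element": "H",
   "type": "H",
   "charge": 0.3
  },
  {
   "name": "CH3",
   "element": "C",
   "type": "CT",
   "charge": 0.02
  },
  {
   "name": "HH31",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HH32",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HH33",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  }
 ],
 "bonds": [
  [
   "CH3",
   "HH31"
  ],
  [
   "CH3",
   "HH32"
  ],
  [
   "CH3",
   "HH33"
  ],
  [
   "N",
   "CH3"
  ],
  [
   "N",
   "H"
  ]
 ],
 "backbone_atoms": [],
 "sidechain_atoms": [],
 "zmatrix": [],
 "chi_atoms": {}
}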