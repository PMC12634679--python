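{
 "name": "ACE",
 "formal_charge": 0,
 "atoms": [
  {
   "name": "CH3",
   "element": "C",
   "type": "CT",
   "charge": -0.18
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
  },
  {
   "name": "C",
   "element": "C",
   "type": "C",
   "charge": 0.5
  },
  {
   "name": "O",
   "element": "O",
   "type": "O",
   "charge": -0.5
  }
 ],
 "bonds": [
  [
   "C",
   "CH3"
  ],
  [
   "C",
   "O"
  ],
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
  ]
 ],
 "backbone_atoms": [],
 "sidechain_atoms": [],
 "zmatrix": [],
 "chi_atoms": {}
}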