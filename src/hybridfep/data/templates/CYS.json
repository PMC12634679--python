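{
 "name": "CYS",
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
   "name": "CA",
   "element": "C",
   "type": "CT",
   "charge": 0.14
  },
  {
   "name": "HA",
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
  },
  {
   "name": "CB",
   "element": "C",
   "type": "CT",
   "charge": 0.06
  },
  {
   "name": "SG",
   "element": "S",
   "type": "SH",
   "charge": -0.335
  },
  {
   "name": "HB2",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HB3",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG",
   "element": "H",
   "type": "HS",
   "charge": 0.155
  }
 ],
 "bonds": [
  [
   "C",
   "CA"
  ],
  [
   "C",
   "O"
  ],
  [
   "CA",
   "CB"
  ],
  [
   "CA",
   "HA"
  ],
  [
   "CA",
   "N"
  ],
  [
   "CB",
   "HB2"
  ],
  [
   "CB",
   "HB3"
  ],
  [
   "CB",
   "SG"
  ],
  [
   "H",
   "N"
  ],
  [
   "HG",
   "SG"
  ]
 ],
 "backbone_atoms": [
  "N",
  "H",
  "CA",
  "HA",
  "C",
  "O"
 ],
 "sidechain_atoms": [
  "CB",
  "SG",
  "HB2",
  "HB3",
  "HG"
 ],
 "zmatrix": [
  {
   "name": "CB",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.528,
   "angle": 109.5,
   "torsion": -120.01,
   "chi": null
  },
  {
   "name": "SG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.814,
   "angle": 109.5,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "SG"
   ],
   "length": 1.09,
   "angle": 109.47,
   "torsion": 119.98,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "SG"
   ],
   "length": 1.09,
   "angle": 109.44,
   "torsion": -120.02,
   "chi": null
  },
  {
   "name": "HG",
   "refs": [
    "SG",
    "CB",
    "CA"
   ],
   "length": 1.344,
   "angle": 100.03,
   "torsion": -179.96,
   "chi": null
  }
 ],
 "chi_atoms": {
  "1": [
   "N",
   "CA",
   "CB",
   "SG"
  ]
 }
}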