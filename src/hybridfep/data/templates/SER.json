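{
 "name": "SER",
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
   "charge": 0.145
  },
  {
   "name": "OG",
   "element": "O",
   "type": "OH",
   "charge": -0.683
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
   "type": "HO",
   "charge": 0.418
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
   "OG"
  ],
  [
   "H",
   "N"
  ],
  [
   "HG",
   "OG"
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
  "OG",
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
   "length": 1.529,
   "angle": 109.47,
   "torsion": -120.02,
   "chi": null
  },
  {
   "name": "OG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.428,
   "angle": 109.51,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "OG"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": 120.01,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "OG"
   ],
   "length": 1.09,
   "angle": 109.48,
   "torsion": -120.04,
   "chi": null
  },
  {
   "name": "HG",
   "refs": [
    "OG",
    "CB",
    "CA"
   ],
   "length": 0.967,
   "angle": 106.81,
   "torsion": -179.97,
   "chi": null
  }
 ],
 "chi_atoms": {
  "1": [
   "N",
   "CA",
   "CB",
   "OG"
  ]
 }
}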