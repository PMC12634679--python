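{
 "name": "MET",
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
   "charge": -0.12
  },
  {
   "name": "CG",
   "element": "C",
   "type": "CT",
   "charge": 0.0975
  },
  {
   "name": "SD",
   "element": "S",
   "type": "S",
   "charge": -0.435
  },
  {
   "name": "CE",
   "element": "C",
   "type": "CT",
   "charge": 0.0375
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
   "name": "HG2",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG3",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HE1",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HE2",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HE3",
   "element": "H",
   "type": "HC",
   "charge": 0.06
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
   "CG"
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
   "CE",
   "HE1"
  ],
  [
   "CE",
   "HE2"
  ],
  [
   "CE",
   "HE3"
  ],
  [
   "CE",
   "SD"
  ],
  [
   "CG",
   "HG2"
  ],
  [
   "CG",
   "HG3"
  ],
  [
   "CG",
   "SD"
  ],
  [
   "H",
   "N"
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
  "CG",
  "SD",
  "CE",
  "HB2",
  "HB3",
  "HG2",
  "HG3",
  "HE1",
  "HE2",
  "HE3"
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
   "angle": 109.43,
   "torsion": -120.04,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.528,
   "angle": 109.54,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "SD",
   "refs": [
    "CG",
    "CB",
    "CA"
   ],
   "length": 1.814,
   "angle": 109.51,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "CE",
   "refs": [
    "SD",
    "CG",
    "CB"
   ],
   "length": 1.814,
   "angle": 100.03,
   "torsion": 180.0,
   "chi": 3
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.09,
   "angle": 109.44,
   "torsion": -120.04,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.091,
   "angle": 109.46,
   "torsion": 120.05,
   "chi": null
  },
  {
   "name": "HG2",
   "refs": [
    "CG",
    "CB",
    "SD"
   ],
   "length": 1.09,
   "angle": 109.46,
   "torsion": -119.98,
   "chi": null
  },
  {
   "name": "HG3",
   "refs": [
    "CG",
    "CB",
    "SD"
   ],
   "length": 1.09,
   "angle": 109.48,
   "torsion": 120.02,
   "chi": null
  },
  {
   "name": "HE1",
   "refs": [
    "CE",
    "SD",
    "CG"
   ],
   "length": 1.089,
   "angle": 109.55,
   "torsion": 179.97,
   "chi": null
  },
  {
   "name": "HE2",
   "refs": [
    "CE",
    "SD",
    "CG"
   ],
   "length": 1.089,
   "angle": 109.46,
   "torsion": -60.0,
   "chi": null
  },
  {
   "name": "HE3",
   "refs": [
    "CE",
    "SD",
    "CG"
   ],
   "length": 1.09,
   "angle": 109.45,
   "torsion": 60.03,
   "chi": null
  }
 ],
 "chi_atoms": {
  "1": [
   "N",
   "CA",
   "CB",
   "CG"
  ],
  "2": [
   "CA",
   "CB",
   "CG",
   "SD"
  ],
  "3": [
   "CB",
   "CG",
   "SD",
   "CE"
  ]
 }
}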