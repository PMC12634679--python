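{
 "name": "ASN",
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
   "type": "C",
   "charge": 0.5
  },
  {
   "name": "OD1",
   "element": "O",
   "type": "O",
   "charge": -0.5
  },
  {
   "name": "ND2",
   "element": "N",
   "type": "N",
   "charge": -0.76
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
   "name": "HD21",
   "element": "H",
   "type": "H",
   "charge": 0.38
  },
  {
   "name": "HD22",
   "element": "H",
   "type": "H",
   "charge": 0.38
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
   "CG",
   "ND2"
  ],
  [
   "CG",
   "OD1"
  ],
  [
   "H",
   "N"
  ],
  [
   "HD21",
   "ND2"
  ],
  [
   "HD22",
   "ND2"
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
  "OD1",
  "ND2",
  "HB2",
  "HB3",
  "HD21",
  "HD22"
 ],
 "zmatrix": [
  {
   "name": "CB",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.531,
   "angle": 109.45,
   "torsion": -120.0,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.507,
   "angle": 109.48,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "OD1",
   "refs": [
    "CG",
    "CB",
    "CA"
   ],
   "length": 1.213,
   "angle": 119.97,
   "torsion": 90.0,
   "chi": 2
  },
  {
   "name": "ND2",
   "refs": [
    "CG",
    "CB",
    "OD1"
   ],
   "length": 1.348,
   "angle": 120.01,
   "torsion": -179.93,
   "chi": null
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.09,
   "angle": 109.41,
   "torsion": 119.97,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.089,
   "angle": 109.47,
   "torsion": -120.03,
   "chi": null
  },
  {
   "name": "HD21",
   "refs": [
    "ND2",
    "CG",
    "OD1"
   ],
   "length": 0.97,
   "angle": 119.99,
   "torsion": -179.98,
   "chi": null
  },
  {
   "name": "HD22",
   "refs": [
    "ND2",
    "CG",
    "OD1"
   ],
   "length": 0.97,
   "angle": 120.06,
   "torsion": 0.06,
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
   "OD1"
  ]
 }
}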