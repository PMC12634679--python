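{
 "name": "ASP",
 "formal_charge": -1,
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
   "charge": -0.22
  },
  {
   "name": "CG",
   "element": "C",
   "type": "CO2",
   "charge": 0.7
  },
  {
   "name": "OD1",
   "element": "O",
   "type": "O2",
   "charge": -0.8
  },
  {
   "name": "OD2",
   "element": "O",
   "type": "O2",
   "charge": -0.8
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
   "OD1"
  ],
  [
   "CG",
   "OD2"
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
  "OD1",
  "OD2",
  "HB2",
  "HB3"
 ],
 "zmatrix": [
  {
   "name": "CB",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.53,
   "angle": 109.48,
   "torsion": -120.01,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.508,
   "angle": 109.46,
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
   "length": 1.208,
   "angle": 119.96,
   "torsion": 90.0,
   "chi": 2
  },
  {
   "name": "OD2",
   "refs": [
    "CG",
    "CB",
    "OD1"
   ],
   "length": 1.341,
   "angle": 120.0,
   "torsion": -179.94,
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
   "angle": 109.49,
   "torsion": 119.96,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.09,
   "angle": 109.49,
   "torsion": -120.01,
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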