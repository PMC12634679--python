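{
 "name": "GLU",
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
   "charge": -0.12
  },
  {
   "name": "CG",
   "element": "C",
   "type": "CT",
   "charge": -0.22
  },
  {
   "name": "CD",
   "element": "C",
   "type": "CO2",
   "charge": 0.7
  },
  {
   "name": "OE1",
   "element": "O",
   "type": "O2",
   "charge": -0.8
  },
  {
   "name": "OE2",
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
   "CD",
   "CG"
  ],
  [
   "CD",
   "OE1"
  ],
  [
   "CD",
   "OE2"
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
  "CD",
  "OE1",
  "OE2",
  "HB2",
  "HB3",
  "HG2",
  "HG3"
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
   "torsion": -119.96,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.531,
   "angle": 109.4,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "CD",
   "refs": [
    "CG",
    "CB",
    "CA"
   ],
   "length": 1.508,
   "angle": 109.43,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "OE1",
   "refs": [
    "CD",
    "CG",
    "CB"
   ],
   "length": 1.208,
   "angle": 120.0,
   "torsion": 180.0,
   "chi": 3
  },
  {
   "name": "OE2",
   "refs": [
    "CD",
    "CG",
    "OE1"
   ],
   "length": 1.343,
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
   "angle": 109.51,
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
   "length": 1.089,
   "angle": 109.5,
   "torsion": -119.98,
   "chi": null
  },
  {
   "name": "HG2",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.09,
   "angle": 109.5,
   "torsion": 119.97,
   "chi": null
  },
  {
   "name": "HG3",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.089,
   "angle": 109.45,
   "torsion": -119.95,
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
   "CD"
  ],
  "3": [
   "CB",
   "CG",
   "CD",
   "OE1"
  ]
 }
}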