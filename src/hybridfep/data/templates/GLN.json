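{
 "name": "GLN",
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
   "charge": -0.12
  },
  {
   "name": "CD",
   "element": "C",
   "type": "C",
   "charge": 0.5
  },
  {
   "name": "OE1",
   "element": "O",
   "type": "O",
   "charge": -0.5
  },
  {
   "name": "NE2",
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
   "name": "HE21",
   "element": "H",
   "type": "H",
   "charge": 0.38
  },
  {
   "name": "HE22",
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
   "CD",
   "CG"
  ],
  [
   "CD",
   "NE2"
  ],
  [
   "CD",
   "OE1"
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
  ],
  [
   "HE21",
   "NE2"
  ],
  [
   "HE22",
   "NE2"
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
  "NE2",
  "HB2",
  "HB3",
  "HG2",
  "HG3",
  "HE21",
  "HE22"
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
   "angle": 109.46,
   "torsion": -120.07,
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
   "angle": 109.53,
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
   "length": 1.507,
   "angle": 109.54,
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
   "length": 1.212,
   "angle": 119.94,
   "torsion": 180.0,
   "chi": 3
  },
  {
   "name": "NE2",
   "refs": [
    "CD",
    "CG",
    "OE1"
   ],
   "length": 1.347,
   "angle": 120.09,
   "torsion": -179.96,
   "chi": null
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.091,
   "angle": 109.42,
   "torsion": 119.99,
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
   "angle": 109.44,
   "torsion": -120.11,
   "chi": null
  },
  {
   "name": "HG2",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.091,
   "angle": 109.46,
   "torsion": 119.96,
   "chi": null
  },
  {
   "name": "HG3",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.09,
   "angle": 109.5,
   "torsion": -120.08,
   "chi": null
  },
  {
   "name": "HE21",
   "refs": [
    "NE2",
    "CD",
    "OE1"
   ],
   "length": 0.969,
   "angle": 120.12,
   "torsion": 0.03,
   "chi": null
  },
  {
   "name": "HE22",
   "refs": [
    "NE2",
    "CD",
    "OE1"
   ],
   "length": 0.97,
   "angle": 119.96,
   "torsion": -179.96,
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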