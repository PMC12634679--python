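{
 "name": "TRP",
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
   "type": "CC",
   "charge": -0.139
  },
  {
   "name": "CD1",
   "element": "C",
   "type": "CW",
   "charge": 0.044
  },
  {
   "name": "CD2",
   "element": "C",
   "type": "CBA",
   "charge": 0.0
  },
  {
   "name": "NE1",
   "element": "N",
   "type": "NA",
   "charge": -0.57
  },
  {
   "name": "CE2",
   "element": "C",
   "type": "CN",
   "charge": 0.13
  },
  {
   "name": "CE3",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CZ2",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CZ3",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CH2",
   "element": "C",
   "type": "CA",
   "charge": -0.115
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
   "name": "HD1",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HE1",
   "element": "H",
   "type": "H",
   "charge": 0.42
  },
  {
   "name": "HE3",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HZ2",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HZ3",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HH2",
   "element": "H",
   "type": "HA",
   "charge": 0.115
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
   "CD1",
   "CG"
  ],
  [
   "CD1",
   "HD1"
  ],
  [
   "CD1",
   "NE1"
  ],
  [
   "CD2",
   "CE2"
  ],
  [
   "CD2",
   "CE3"
  ],
  [
   "CD2",
   "CG"
  ],
  [
   "CE2",
   "CZ2"
  ],
  [
   "CE2",
   "NE1"
  ],
  [
   "CE3",
   "CZ3"
  ],
  [
   "CE3",
   "HE3"
  ],
  [
   "CH2",
   "CZ2"
  ],
  [
   "CH2",
   "CZ3"
  ],
  [
   "CH2",
   "HH2"
  ],
  [
   "CZ2",
   "HZ2"
  ],
  [
   "CZ3",
   "HZ3"
  ],
  [
   "H",
   "N"
  ],
  [
   "HE1",
   "NE1"
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
  "CD1",
  "CD2",
  "NE1",
  "CE2",
  "CE3",
  "CZ2",
  "CZ3",
  "CH2",
  "HB2",
  "HB3",
  "HD1",
  "HE1",
  "HE3",
  "HZ2",
  "HZ3",
  "HH2"
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
   "angle": 109.52,
   "torsion": -120.03,
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
   "angle": 109.44,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "CD1",
   "refs": [
    "CG",
    "CB",
    "CA"
   ],
   "length": 1.343,
   "angle": 126.5,
   "torsion": 90.0,
   "chi": 2
  },
  {
   "name": "CD2",
   "refs": [
    "CG",
    "CB",
    "CD1"
   ],
   "length": 1.464,
   "angle": 126.51,
   "torsion": 179.62,
   "chi": null
  },
  {
   "name": "NE1",
   "refs": [
    "CD1",
    "CG",
    "CD2"
   ],
   "length": 1.369,
   "angle": 109.93,
   "torsion": 0.26,
   "chi": null
  },
  {
   "name": "CE2",
   "refs": [
    "CD2",
    "CG",
    "CD1"
   ],
   "length": 1.407,
   "angle": 106.08,
   "torsion": -0.36,
   "chi": null
  },
  {
   "name": "CE3",
   "refs": [
    "CD2",
    "CG",
    "CD1"
   ],
   "length": 1.396,
   "angle": 134.05,
   "torsion": -179.53,
   "chi": null
  },
  {
   "name": "CZ2",
   "refs": [
    "CE2",
    "CD2",
    "CE3"
   ],
   "length": 1.391,
   "angle": 119.35,
   "torsion": -0.51,
   "chi": null
  },
  {
   "name": "CZ3",
   "refs": [
    "CE3",
    "CD2",
    "CE2"
   ],
   "length": 1.366,
   "angle": 119.8,
   "torsion": 0.55,
   "chi": null
  },
  {
   "name": "CH2",
   "refs": [
    "CZ2",
    "CE2",
    "CD2"
   ],
   "length": 1.377,
   "angle": 119.81,
   "torsion": 0.22,
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
   "angle": 109.47,
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
   "angle": 109.51,
   "torsion": -119.99,
   "chi": null
  },
  {
   "name": "HD1",
   "refs": [
    "CD1",
    "NE1",
    "CE2"
   ],
   "length": 1.079,
   "angle": 124.98,
   "torsion": 179.94,
   "chi": null
  },
  {
   "name": "HE1",
   "refs": [
    "NE1",
    "CD1",
    "CG"
   ],
   "length": 0.969,
   "angle": 125.07,
   "torsion": -179.97,
   "chi": null
  },
  {
   "name": "HE3",
   "refs": [
    "CE3",
    "CZ3",
    "CH2"
   ],
   "length": 1.08,
   "angle": 120.13,
   "torsion": -179.99,
   "chi": null
  },
  {
   "name": "HZ2",
   "refs": [
    "CZ2",
    "CH2",
    "CZ3"
   ],
   "length": 1.08,
   "angle": 120.08,
   "torsion": -179.9,
   "chi": null
  },
  {
   "name": "HZ3",
   "refs": [
    "CZ3",
    "CE3",
    "CD2"
   ],
   "length": 1.08,
   "angle": 119.76,
   "torsion": 179.66,
   "chi": null
  },
  {
   "name": "HH2",
   "refs": [
    "CH2",
    "CZ2",
    "CE2"
   ],
   "length": 1.08,
   "angle": 119.64,
   "torsion": 179.96,
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
   "CD1"
  ]
 }
}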