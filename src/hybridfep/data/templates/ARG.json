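{
 "name": "ARG",
 "formal_charge": 1,
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
   "type": "CT",
   "charge": 0.19
  },
  {
   "name": "NE",
   "element": "N",
   "type": "NE",
   "charge": -0.7
  },
  {
   "name": "CZ",
   "element": "C",
   "type": "CZ",
   "charge": 0.71
  },
  {
   "name": "NH1",
   "element": "N",
   "type": "N2",
   "charge": -0.8
  },
  {
   "name": "NH2",
   "element": "N",
   "type": "N2",
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
  },
  {
   "name": "HD2",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD3",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HE",
   "element": "H",
   "type": "H",
   "charge": 0.44
  },
  {
   "name": "HH11",
   "element": "H",
   "type": "H3",
   "charge": 0.46
  },
  {
   "name": "HH12",
   "element": "H",
   "type": "H3",
   "charge": 0.46
  },
  {
   "name": "HH21",
   "element": "H",
   "type": "H3",
   "charge": 0.46
  },
  {
   "name": "HH22",
   "element": "H",
   "type": "H3",
   "charge": 0.46
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
   "HD2"
  ],
  [
   "CD",
   "HD3"
  ],
  [
   "CD",
   "NE"
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
   "CZ",
   "NE"
  ],
  [
   "CZ",
   "NH1"
  ],
  [
   "CZ",
   "NH2"
  ],
  [
   "H",
   "N"
  ],
  [
   "HE",
   "NE"
  ],
  [
   "HH11",
   "NH1"
  ],
  [
   "HH12",
   "NH1"
  ],
  [
   "HH21",
   "NH2"
  ],
  [
   "HH22",
   "NH2"
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
  "NE",
  "CZ",
  "NH1",
  "NH2",
  "HB2",
  "HB3",
  "HG2",
  "HG3",
  "HD2",
  "HD3",
  "HE",
  "HH11",
  "HH12",
  "HH21",
  "HH22"
 ],
 "zmatrix": [
  {
   "name": "CB",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.536,
   "angle": 111.55,
   "torsion": -123.56,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.537,
   "angle": 114.54,
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
   "length": 1.527,
   "angle": 112.42,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "NE",
   "refs": [
    "CD",
    "CG",
    "CB"
   ],
   "length": 1.444,
   "angle": 111.02,
   "torsion": 180.0,
   "chi": 3
  },
  {
   "name": "CZ",
   "refs": [
    "NE",
    "CD",
    "CG"
   ],
   "length": 1.406,
   "angle": 123.0,
   "torsion": 180.0,
   "chi": 4
  },
  {
   "name": "NH1",
   "refs": [
    "CZ",
    "NE",
    "CD"
   ],
   "length": 1.391,
   "angle": 121.0,
   "torsion": 179.99,
   "chi": null
  },
  {
   "name": "NH2",
   "refs": [
    "CZ",
    "NE",
    "NH1"
   ],
   "length": 1.391,
   "angle": 119.81,
   "torsion": -180.0,
   "chi": null
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.097,
   "angle": 108.91,
   "torsion": -122.42,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.098,
   "angle": 108.84,
   "torsion": 122.12,
   "chi": null
  },
  {
   "name": "HG2",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.097,
   "angle": 109.55,
   "torsion": -120.1,
   "chi": null
  },
  {
   "name": "HG3",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.097,
   "angle": 110.03,
   "torsion": 122.38,
   "chi": null
  },
  {
   "name": "HD2",
   "refs": [
    "CD",
    "CG",
    "NE"
   ],
   "length": 1.095,
   "angle": 109.48,
   "torsion": 119.82,
   "chi": null
  },
  {
   "name": "HD3",
   "refs": [
    "CD",
    "CG",
    "NE"
   ],
   "length": 1.095,
   "angle": 110.63,
   "torsion": -121.94,
   "chi": null
  },
  {
   "name": "HE",
   "refs": [
    "NE",
    "CD",
    "CZ"
   ],
   "length": 1.027,
   "angle": 120.43,
   "torsion": -179.83,
   "chi": null
  },
  {
   "name": "HH11",
   "refs": [
    "NH1",
    "CZ",
    "NE"
   ],
   "length": 1.018,
   "angle": 120.9,
   "torsion": -179.96,
   "chi": null
  },
  {
   "name": "HH12",
   "refs": [
    "NH1",
    "CZ",
    "NE"
   ],
   "length": 1.016,
   "angle": 121.94,
   "torsion": 0.2,
   "chi": null
  },
  {
   "name": "HH21",
   "refs": [
    "NH2",
    "CZ",
    "NE"
   ],
   "length": 1.017,
   "angle": 121.2,
   "torsion": 0.06,
   "chi": null
  },
  {
   "name": "HH22",
   "refs": [
    "NH2",
    "CZ",
    "NE"
   ],
   "length": 1.017,
   "angle": 121.17,
   "torsion": 179.91,
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
   "NE"
  ],
  "4": [
   "CG",
   "CD",
   "NE",
   "CZ"
  ]
 }
}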