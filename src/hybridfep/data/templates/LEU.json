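{
 "name": "LEU",
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
   "charge": -0.06
  },
  {
   "name": "CD1",
   "element": "C",
   "type": "CT",
   "charge": -0.18
  },
  {
   "name": "CD2",
   "element": "C",
   "type": "CT",
   "charge": -0.18
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
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD11",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD12",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD13",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD21",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD22",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HD23",
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
   "CD1",
   "CG"
  ],
  [
   "CD1",
   "HD11"
  ],
  [
   "CD1",
   "HD12"
  ],
  [
   "CD1",
   "HD13"
  ],
  [
   "CD2",
   "CG"
  ],
  [
   "CD2",
   "HD21"
  ],
  [
   "CD2",
   "HD22"
  ],
  [
   "CD2",
   "HD23"
  ],
  [
   "CG",
   "HG"
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
  "CD1",
  "CD2",
  "HB2",
  "HB3",
  "HG",
  "HD11",
  "HD12",
  "HD13",
  "HD21",
  "HD22",
  "HD23"
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
   "angle": 109.42,
   "torsion": -119.97,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.53,
   "angle": 109.49,
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
   "length": 1.53,
   "angle": 109.5,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "CD2",
   "refs": [
    "CG",
    "CB",
    "CD1"
   ],
   "length": 1.529,
   "angle": 109.5,
   "torsion": 120.09,
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
   "angle": 109.46,
   "torsion": -119.96,
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
   "angle": 109.54,
   "torsion": 120.08,
   "chi": null
  },
  {
   "name": "HG",
   "refs": [
    "CG",
    "CB",
    "CD1"
   ],
   "length": 1.09,
   "angle": 109.4,
   "torsion": -119.86,
   "chi": null
  },
  {
   "name": "HD11",
   "refs": [
    "CD1",
    "CG",
    "CB"
   ],
   "length": 1.089,
   "angle": 109.49,
   "torsion": 179.98,
   "chi": null
  },
  {
   "name": "HD12",
   "refs": [
    "CD1",
    "CG",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.51,
   "torsion": -59.88,
   "chi": null
  },
  {
   "name": "HD13",
   "refs": [
    "CD1",
    "CG",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.45,
   "torsion": 60.04,
   "chi": null
  },
  {
   "name": "HD21",
   "refs": [
    "CD2",
    "CG",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": -60.05,
   "chi": null
  },
  {
   "name": "HD22",
   "refs": [
    "CD2",
    "CG",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.5,
   "torsion": 59.94,
   "chi": null
  },
  {
   "name": "HD23",
   "refs": [
    "CD2",
    "CG",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.48,
   "torsion": 179.98,
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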