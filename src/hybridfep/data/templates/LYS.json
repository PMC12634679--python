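{
 "name": "LYS",
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
   "charge": -0.12
  },
  {
   "name": "CE",
   "element": "C",
   "type": "CT",
   "charge": 0.19
  },
  {
   "name": "NZ",
   "element": "N",
   "type": "N3",
   "charge": -0.4
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
   "name": "HE2",
   "element": "H",
   "type": "HC",
   "charge": 0.11
  },
  {
   "name": "HE3",
   "element": "H",
   "type": "HC",
   "charge": 0.11
  },
  {
   "name": "HZ1",
   "element": "H",
   "type": "H3",
   "charge": 0.33
  },
  {
   "name": "HZ2",
   "element": "H",
   "type": "H3",
   "charge": 0.33
  },
  {
   "name": "HZ3",
   "element": "H",
   "type": "H3",
   "charge": 0.33
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
   "CE"
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
   "CE",
   "HE2"
  ],
  [
   "CE",
   "HE3"
  ],
  [
   "CE",
   "NZ"
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
   "HZ1",
   "NZ"
  ],
  [
   "HZ2",
   "NZ"
  ],
  [
   "HZ3",
   "NZ"
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
  "CE",
  "NZ",
  "HB2",
  "HB3",
  "HG2",
  "HG3",
  "HD2",
  "HD3",
  "HE2",
  "HE3",
  "HZ1",
  "HZ2",
  "HZ3"
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
   "angle": 109.45,
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
   "length": 1.531,
   "angle": 109.42,
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
   "length": 1.531,
   "angle": 109.44,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "CE",
   "refs": [
    "CD",
    "CG",
    "CB"
   ],
   "length": 1.529,
   "angle": 109.46,
   "torsion": 180.0,
   "chi": 3
  },
  {
   "name": "NZ",
   "refs": [
    "CE",
    "CD",
    "CG"
   ],
   "length": 1.469,
   "angle": 109.5,
   "torsion": 180.0,
   "chi": 4
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.089,
   "angle": 109.51,
   "torsion": 120.02,
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
   "torsion": -119.94,
   "chi": null
  },
  {
   "name": "HG2",
   "refs": [
    "CG",
    "CB",
    "CD"
   ],
   "length": 1.089,
   "angle": 109.47,
   "torsion": 119.98,
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
   "angle": 109.49,
   "torsion": -119.94,
   "chi": null
  },
  {
   "name": "HD2",
   "refs": [
    "CD",
    "CG",
    "CE"
   ],
   "length": 1.09,
   "angle": 109.5,
   "torsion": 120.04,
   "chi": null
  },
  {
   "name": "HD3",
   "refs": [
    "CD",
    "CG",
    "CE"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": -119.98,
   "chi": null
  },
  {
   "name": "HE2",
   "refs": [
    "CE",
    "CD",
    "NZ"
   ],
   "length": 1.09,
   "angle": 109.53,
   "torsion": 119.97,
   "chi": null
  },
  {
   "name": "HE3",
   "refs": [
    "CE",
    "CD",
    "NZ"
   ],
   "length": 1.09,
   "angle": 109.5,
   "torsion": -120.05,
   "chi": null
  },
  {
   "name": "HZ1",
   "refs": [
    "NZ",
    "CE",
    "CD"
   ],
   "length": 1.009,
   "angle": 109.37,
   "torsion": -60.0,
   "chi": null
  },
  {
   "name": "HZ2",
   "refs": [
    "NZ",
    "CE",
    "CD"
   ],
   "length": 1.008,
   "angle": 109.47,
   "torsion": 59.95,
   "chi": null
  },
  {
   "name": "HZ3",
   "refs": [
    "NZ",
    "CE",
    "CD"
   ],
   "length": 1.009,
   "angle": 109.53,
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
   "CE"
  ],
  "4": [
   "CG",
   "CD",
   "CE",
   "NZ"
  ]
 }
}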