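{
 "name": "TYR",
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
   "type": "CAJ",
   "charge": -0.0
  },
  {
   "name": "CD1",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CD2",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CE1",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CE2",
   "element": "C",
   "type": "CA",
   "charge": -0.115
  },
  {
   "name": "CZ",
   "element": "C",
   "type": "CAO",
   "charge": 0.15
  },
  {
   "name": "OH",
   "element": "O",
   "type": "OH",
   "charge": -0.585
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
   "name": "HD2",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HE1",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HE2",
   "element": "H",
   "type": "HA",
   "charge": 0.115
  },
  {
   "name": "HH",
   "element": "H",
   "type": "HO",
   "charge": 0.435
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
   "CE1"
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
   "CD2",
   "CE2"
  ],
  [
   "CD2",
   "CG"
  ],
  [
   "CD2",
   "HD2"
  ],
  [
   "CE1",
   "CZ"
  ],
  [
   "CE1",
   "HE1"
  ],
  [
   "CE2",
   "CZ"
  ],
  [
   "CE2",
   "HE2"
  ],
  [
   "CZ",
   "OH"
  ],
  [
   "H",
   "N"
  ],
  [
   "HH",
   "OH"
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
  "CE1",
  "CE2",
  "CZ",
  "OH",
  "HB2",
  "HB3",
  "HD1",
  "HD2",
  "HE1",
  "HE2",
  "HH"
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
   "length": 1.506,
   "angle": 109.5,
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
   "length": 1.382,
   "angle": 119.95,
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
   "length": 1.383,
   "angle": 119.94,
   "torsion": 179.69,
   "chi": null
  },
  {
   "name": "CE1",
   "refs": [
    "CD1",
    "CG",
    "CB"
   ],
   "length": 1.381,
   "angle": 120.07,
   "torsion": -179.98,
   "chi": null
  },
  {
   "name": "CE2",
   "refs": [
    "CD2",
    "CG",
    "CB"
   ],
   "length": 1.381,
   "angle": 120.02,
   "torsion": 179.77,
   "chi": null
  },
  {
   "name": "CZ",
   "refs": [
    "CE1",
    "CD1",
    "CG"
   ],
   "length": 1.387,
   "angle": 119.98,
   "torsion": -0.1,
   "chi": null
  },
  {
   "name": "OH",
   "refs": [
    "CZ",
    "CE1",
    "CD1"
   ],
   "length": 1.358,
   "angle": 120.13,
   "torsion": -179.97,
   "chi": null
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
   "torsion": 120.1,
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
   "torsion": -119.99,
   "chi": null
  },
  {
   "name": "HD1",
   "refs": [
    "CD1",
    "CE1",
    "CZ"
   ],
   "length": 1.079,
   "angle": 119.99,
   "torsion": 179.89,
   "chi": null
  },
  {
   "name": "HD2",
   "refs": [
    "CD2",
    "CE2",
    "CZ"
   ],
   "length": 1.08,
   "angle": 119.98,
   "torsion": -179.96,
   "chi": null
  },
  {
   "name": "HE1",
   "refs": [
    "CE1",
    "CD1",
    "CG"
   ],
   "length": 1.08,
   "angle": 120.06,
   "torsion": 179.95,
   "chi": null
  },
  {
   "name": "HE2",
   "refs": [
    "CE2",
    "CD2",
    "CG"
   ],
   "length": 1.08,
   "angle": 120.04,
   "torsion": -179.66,
   "chi": null
  },
  {
   "name": "HH",
   "refs": [
    "OH",
    "CZ",
    "CE1"
   ],
   "length": 0.966,
   "angle": 106.88,
   "torsion": 90.04,
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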