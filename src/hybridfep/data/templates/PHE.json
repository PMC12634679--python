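{
 "name": "PHE",
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
   "charge": 0.0
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
   "name": "HZ",
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
   "HZ"
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
  "CE1",
  "CE2",
  "CZ",
  "HB2",
  "HB3",
  "HD1",
  "HD2",
  "HE1",
  "HE2",
  "HZ"
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
   "torsion": -120.09,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.505,
   "angle": 109.52,
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
   "angle": 120.06,
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
   "angle": 120.0,
   "torsion": 179.76,
   "chi": null
  },
  {
   "name": "CE1",
   "refs": [
    "CD1",
    "CG",
    "CB"
   ],
   "length": 1.382,
   "angle": 120.03,
   "torsion": 179.99,
   "chi": null
  },
  {
   "name": "CE2",
   "refs": [
    "CD2",
    "CG",
    "CB"
   ],
   "length": 1.382,
   "angle": 119.98,
   "torsion": 179.84,
   "chi": null
  },
  {
   "name": "CZ",
   "refs": [
    "CE1",
    "CD1",
    "CG"
   ],
   "length": 1.381,
   "angle": 120.05,
   "torsion": -0.05,
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
   "angle": 109.44,
   "torsion": 120.05,
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
   "torsion": -120.07,
   "chi": null
  },
  {
   "name": "HD1",
   "refs": [
    "CD1",
    "CE1",
    "CZ"
   ],
   "length": 1.08,
   "angle": 120.02,
   "torsion": 179.91,
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
   "angle": 120.05,
   "torsion": -179.93,
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
   "angle": 119.98,
   "torsion": 179.97,
   "chi": null
  },
  {
   "name": "HE2",
   "refs": [
    "CE2",
    "CD2",
    "CG"
   ],
   "length": 1.081,
   "angle": 119.93,
   "torsion": -179.73,
   "chi": null
  },
  {
   "name": "HZ",
   "refs": [
    "CZ",
    "CE1",
    "CD1"
   ],
   "length": 1.08,
   "angle": 120.07,
   "torsion": 179.94,
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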