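{
 "name": "HIS",
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
   "charge": 0.38
  },
  {
   "name": "ND1",
   "element": "N",
   "type": "NB",
   "charge": -0.56
  },
  {
   "name": "CD2",
   "element": "C",
   "type": "CV",
   "charge": -0.22
  },
  {
   "name": "CE1",
   "element": "C",
   "type": "CR",
   "charge": 0.25
  },
  {
   "name": "NE2",
   "element": "N",
   "type": "NA",
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
   "type": "H",
   "charge": 0.32
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
   "CD2",
   "CG"
  ],
  [
   "CD2",
   "HD2"
  ],
  [
   "CD2",
   "NE2"
  ],
  [
   "CE1",
   "HE1"
  ],
  [
   "CE1",
   "ND1"
  ],
  [
   "CE1",
   "NE2"
  ],
  [
   "CG",
   "ND1"
  ],
  [
   "H",
   "N"
  ],
  [
   "HE2",
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
  "ND1",
  "CD2",
  "CE1",
  "NE2",
  "HB2",
  "HB3",
  "HD2",
  "HE1",
  "HE2"
 ],
 "zmatrix": [
  {
   "name": "CB",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.534,
   "angle": 111.13,
   "torsion": -122.78,
   "chi": null
  },
  {
   "name": "CG",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.51,
   "angle": 112.98,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "ND1",
   "refs": [
    "CG",
    "CB",
    "CA"
   ],
   "length": 1.351,
   "angle": 120.33,
   "torsion": 90.0,
   "chi": 2
  },
  {
   "name": "CD2",
   "refs": [
    "CG",
    "CB",
    "ND1"
   ],
   "length": 1.338,
   "angle": 129.93,
   "torsion": 179.85,
   "chi": null
  },
  {
   "name": "CE1",
   "refs": [
    "ND1",
    "CG",
    "CD2"
   ],
   "length": 1.337,
   "angle": 107.86,
   "torsion": 0.03,
   "chi": null
  },
  {
   "name": "NE2",
   "refs": [
    "CD2",
    "CG",
    "ND1"
   ],
   "length": 1.374,
   "angle": 105.33,
   "torsion": -0.01,
   "chi": null
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "CG"
   ],
   "length": 1.099,
   "angle": 110.38,
   "torsion": 121.12,
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
   "angle": 110.2,
   "torsion": -123.09,
   "chi": null
  },
  {
   "name": "HD2",
   "refs": [
    "CD2",
    "NE2",
    "CE1"
   ],
   "length": 1.072,
   "angle": 117.52,
   "torsion": -179.9,
   "chi": null
  },
  {
   "name": "HE1",
   "refs": [
    "CE1",
    "ND1",
    "CG"
   ],
   "length": 1.078,
   "angle": 126.18,
   "torsion": 179.99,
   "chi": null
  },
  {
   "name": "HE2",
   "refs": [
    "NE2",
    "CD2",
    "CG"
   ],
   "length": 1.016,
   "angle": 125.48,
   "torsion": 179.93,
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
   "ND1"
  ]
 }
}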