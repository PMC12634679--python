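{
 "name": "ILE",
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
   "charge": -0.06
  },
  {
   "name": "CG1",
   "element": "C",
   "type": "CT",
   "charge": -0.12
  },
  {
   "name": "CG2",
   "element": "C",
   "type": "CT",
   "charge": -0.18
  },
  {
   "name": "CD1",
   "element": "C",
   "type": "CT",
   "charge": -0.18
  },
  {
   "name": "HB",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG12",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG13",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG21",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG22",
   "element": "H",
   "type": "HC",
   "charge": 0.06
  },
  {
   "name": "HG23",
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
   "CG1"
  ],
  [
   "CB",
   "CG2"
  ],
  [
   "CB",
   "HB"
  ],
  [
   "CD1",
   "CG1"
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
   "CG1",
   "HG12"
  ],
  [
   "CG1",
   "HG13"
  ],
  [
   "CG2",
   "HG21"
  ],
  [
   "CG2",
   "HG22"
  ],
  [
   "CG2",
   "HG23"
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
  "CG1",
  "CG2",
  "CD1",
  "HB",
  "HG12",
  "HG13",
  "HG21",
  "HG22",
  "HG23",
  "HD11",
  "HD12",
  "HD13"
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
   "angle": 109.43,
   "torsion": -120.07,
   "chi": null
  },
  {
   "name": "CG1",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.529,
   "angle": 109.55,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "CG2",
   "refs": [
    "CB",
    "CA",
    "CG1"
   ],
   "length": 1.53,
   "angle": 109.46,
   "torsion": -119.97,
   "chi": null
  },
  {
   "name": "CD1",
   "refs": [
    "CG1",
    "CB",
    "CA"
   ],
   "length": 1.529,
   "angle": 109.55,
   "torsion": 180.0,
   "chi": 2
  },
  {
   "name": "HB",
   "refs": [
    "CB",
    "CA",
    "CG1"
   ],
   "length": 1.089,
   "angle": 109.48,
   "torsion": 120.09,
   "chi": null
  },
  {
   "name": "HG12",
   "refs": [
    "CG1",
    "CB",
    "CD1"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": -119.97,
   "chi": null
  },
  {
   "name": "HG13",
   "refs": [
    "CG1",
    "CB",
    "CD1"
   ],
   "length": 1.09,
   "angle": 109.48,
   "torsion": 120.03,
   "chi": null
  },
  {
   "name": "HG21",
   "refs": [
    "CG2",
    "CB",
    "CA"
   ],
   "length": 1.088,
   "angle": 109.48,
   "torsion": 59.97,
   "chi": null
  },
  {
   "name": "HG22",
   "refs": [
    "CG2",
    "CB",
    "CA"
   ],
   "length": 1.09,
   "angle": 109.45,
   "torsion": -179.95,
   "chi": null
  },
  {
   "name": "HG23",
   "refs": [
    "CG2",
    "CB",
    "CA"
   ],
   "length": 1.09,
   "angle": 109.48,
   "torsion": -60.03,
   "chi": null
  },
  {
   "name": "HD11",
   "refs": [
    "CD1",
    "CG1",
    "CB"
   ],
   "length": 1.089,
   "angle": 109.6,
   "torsion": -179.99,
   "chi": null
  },
  {
   "name": "HD12",
   "refs": [
    "CD1",
    "CG1",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.49,
   "torsion": -59.9,
   "chi": null
  },
  {
   "name": "HD13",
   "refs": [
    "CD1",
    "CG1",
    "CB"
   ],
   "length": 1.09,
   "angle": 109.46,
   "torsion": 59.98,
   "chi": null
  }
 ],
 "chi_atoms": {
  "1": [
   "N",
   "CA",
   "CB",
   "CG1"
  ],
  "2": [
   "CA",
   "CB",
   "CG1",
   "CD1"
  ]
 }
}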