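{
 "name": "THR",
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
   "charge": 0.205
  },
  {
   "name": "OG1",
   "element": "O",
   "type": "OH",
   "charge": -0.683
  },
  {
   "name": "CG2",
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
   "name": "HG1",
   "element": "H",
   "type": "HO",
   "charge": 0.418
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
   "CG2"
  ],
  [
   "CB",
   "HB"
  ],
  [
   "CB",
   "OG1"
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
  ],
  [
   "HG1",
   "OG1"
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
  "OG1",
  "CG2",
  "HB",
  "HG1",
  "HG21",
  "HG22",
  "HG23"
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
   "angle": 109.41,
   "torsion": -120.0,
   "chi": null
  },
  {
   "name": "OG1",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.428,
   "angle": 109.51,
   "torsion": -60.0,
   "chi": 1
  },
  {
   "name": "CG2",
   "refs": [
    "CB",
    "CA",
    "OG1"
   ],
   "length": 1.53,
   "angle": 109.53,
   "torsion": -120.03,
   "chi": null
  },
  {
   "name": "HB",
   "refs": [
    "CB",
    "CA",
    "OG1"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": 119.99,
   "chi": null
  },
  {
   "name": "HG1",
   "refs": [
    "OG1",
    "CB",
    "CA"
   ],
   "length": 0.967,
   "angle": 106.81,
   "torsion": -60.06,
   "chi": null
  },
  {
   "name": "HG21",
   "refs": [
    "CG2",
    "CB",
    "CA"
   ],
   "length": 1.089,
   "angle": 109.48,
   "torsion": -179.94,
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
   "angle": 109.47,
   "torsion": -59.94,
   "chi": null
  },
  {
   "name": "HG23",
   "refs": [
    "CG2",
    "CB",
    "CA"
   ],
   "length": 1.089,
   "angle": 109.46,
   "torsion": 60.04,
   "chi": null
  }
 ],
 "chi_atoms": {
  "1": [
   "N",
   "CA",
   "CB",
   "OG1"
  ]
 }
}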