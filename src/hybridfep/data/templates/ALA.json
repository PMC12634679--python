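{
 "name": "ALA",
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
   "charge": -0.18
  },
  {
   "name": "HB1",
   "element": "H",
   "type": "HC",
   "charge": 0.06
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
   "HB1"
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
  "HB1",
  "HB2",
  "HB3"
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
   "torsion": -120.0,
   "chi": null
  },
  {
   "name": "HB1",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.091,
   "angle": 109.49,
   "torsion": -59.97,
   "chi": null
  },
  {
   "name": "HB2",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.09,
   "angle": 109.43,
   "torsion": 60.0,
   "chi": null
  },
  {
   "name": "HB3",
   "refs": [
    "CB",
    "CA",
    "N"
   ],
   "length": 1.09,
   "angle": 109.52,
   "torsion": -179.96,
   "chi": null
  }
 ],
 "chi_atoms": {}
}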