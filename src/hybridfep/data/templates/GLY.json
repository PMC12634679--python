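{
 "name": "GLY",
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
   "name": "HA2",
   "element": "H",
   "type": "HC",
   "charge": 0.0
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
   "HA"
  ],
  [
   "CA",
   "HA2"
  ],
  [
   "CA",
   "N"
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
  "HA2"
 ],
 "zmatrix": [
  {
   "name": "HA2",
   "refs": [
    "CA",
    "N",
    "C"
   ],
   "length": 1.09,
   "angle": 109.45,
   "torsion": -119.97,
   "chi": null
  }
 ],
 "chi_atoms": {}
}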