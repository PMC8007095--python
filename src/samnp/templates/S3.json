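{
 "name": "S3",
 "kind": "ligand",
 "formal_charge": 0,
 "anchor_index": 0,
 "terminal_index": 9,
 "atoms": [
  {
   "element": "S",
   "charge": 0.0,
   "sigma": 3.6,
   "epsilon": 0.25,
   "x": 0.0,
   "y": 0.0,
   "z": 0.0
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 1.2691543304779043
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 2.5383086609558085
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 3.807462991433713
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 5.076617321911617
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 6.345771652389521
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 7.614925982867426
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 8.88408031334533
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 10.153234643823234
  },
  {
   "element": "O",
   "charge": -0.4,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 0.0,
   "y": 0.0,
   "z": 11.422388974301139
  },
  {
   "element": "H",
   "charge": 0.4,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": 0.6,
   "y": 0.0,
   "z": 12.172388974301139
  }
 ],
 "bonds": [
  [
   0,
   1,
   1.81
  ],
  [
   1,
   2,
   1.54
  ],
  [
   2,
   3,
   1.54
  ],
  [
   3,
   4,
   1.54
  ],
  [
   4,
   5,
   1.54
  ],
  [
   5,
   6,
   1.54
  ],
  [
   6,
   7,
   1.54
  ],
  [
   7,
   8,
   1.54
  ],
  [
   8,
   9,
   1.43
  ],
  [
   9,
   10,
   0.97
  ]
 ],
 "group_flags": {
  "10": "hydrogen"
 }
}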