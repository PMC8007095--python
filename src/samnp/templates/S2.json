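{
 "name": "S2",
 "kind": "ligand",
 "formal_charge": -1,
 "anchor_index": 0,
 "terminal_index": 7,
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
   "element": "S",
   "charge": 0.5,
   "sigma": 3.6,
   "epsilon": 0.25,
   "x": 0.0,
   "y": 0.0,
   "z": 9.506594384273274
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 1.371951226347426,
   "y": 0.0,
   "z": 10.00594379352875
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": -0.6859756131737127,
   "y": 1.1881446147700856,
   "z": 10.00594379352875
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": -0.6859756131737137,
   "y": -1.1881446147700852,
   "z": 10.00594379352875
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
   1.81
  ],
  [
   7,
   8,
   1.46
  ],
  [
   7,
   9,
   1.46
  ],
  [
   7,
   10,
   1.46
  ]
 ],
 "group_flags": {
  "8": "sulfonate_oxygen",
  "9": "sulfonate_oxygen",
  "10": "sulfonate_oxygen"
 }
}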