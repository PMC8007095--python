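{
 "name": "S1",
 "kind": "ligand",
 "formal_charge": -1,
 "anchor_index": 0,
 "terminal_index": 12,
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
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 11.422388974301139
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 12.691543304779042
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 13.960697635256947
  },
  {
   "element": "S",
   "charge": 0.5,
   "sigma": 3.6,
   "epsilon": 0.25,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 15.852366036662795
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 2.2442168312116686,
   "y": 0.0,
   "z": 16.351715445918273
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 0.18628999169052984,
   "y": 1.1881446147700856,
   "z": 16.351715445918273
  },
  {
   "element": "O",
   "charge": -0.5,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 0.18628999169052884,
   "y": -1.1881446147700852,
   "z": 16.351715445918273
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
   1.54
  ],
  [
   9,
   10,
   1.54
  ],
  [
   10,
   11,
   1.54
  ],
  [
   11,
   12,
   1.81
  ],
  [
   12,
   13,
   1.46
  ],
  [
   12,
   14,
   1.46
  ],
  [
   12,
   15,
   1.46
  ]
 ],
 "group_flags": {
  "9": "aromatic_carbon",
  "10": "aromatic_carbon",
  "11": "aromatic_carbon",
  "13": "sulfonate_oxygen",
  "14": "sulfonate_oxygen",
  "15": "sulfonate_oxygen"
 }
}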