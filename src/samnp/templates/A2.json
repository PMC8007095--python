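{
 "name": "A2",
 "kind": "analyte",
 "formal_charge": 1,
 "anchor_index": null,
 "terminal_index": 9,
 "atoms": [
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": -1.2691543304779043
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": 0.0
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 8.572527594031472e-17,
   "y": 0.0,
   "z": 4.069154330477904
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": -1.2124355652982137,
   "y": 0.0,
   "z": 3.3691543304779046
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": -1.2124355652982142,
   "y": 0.0,
   "z": 1.9691543304779047
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": -2.5717582782094415e-16,
   "y": 0.0,
   "z": 1.2691543304779045
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 1.2124355652982137,
   "y": 0.0,
   "z": 1.9691543304779038
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 1.212435565298214,
   "y": 0.0,
   "z": 3.3691543304779046
  },
  {
   "element": "N",
   "charge": 0.25,
   "sigma": 3.25,
   "epsilon": 0.17,
   "x": 0.0,
   "y": 0.0,
   "z": 5.549154330477904
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": 0.9364556931124554,
   "y": 0.0,
   "z": 5.927506989827975
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": -0.46822784655622746,
   "y": 0.8109944197539505,
   "z": 5.927506989827975
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": -0.46822784655622807,
   "y": -0.8109944197539501,
   "z": 5.927506989827975
  }
 ],
 "bonds": [
  [
   0,
   1,
   1.54
  ],
  [
   2,
   3,
   1.4
  ],
  [
   3,
   4,
   1.4
  ],
  [
   4,
   5,
   1.4
  ],
  [
   5,
   6,
   1.4
  ],
  [
   6,
   7,
   1.4
  ],
  [
   7,
   2,
   1.4
  ],
  [
   1,
   5,
   1.54
  ],
  [
   2,
   8,
   1.48
  ],
  [
   8,
   9,
   1.01
  ],
  [
   8,
   10,
   1.01
  ],
  [
   8,
   11,
   1.01
  ]
 ],
 "group_flags": {
  "2": "aromatic_carbon",
  "3": "aromatic_carbon",
  "4": "aromatic_carbon",
  "5": "aromatic_carbon",
  "6": "aromatic_carbon",
  "7": "aromatic_carbon",
  "8": "ammonium_nitrogen"
 }
}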