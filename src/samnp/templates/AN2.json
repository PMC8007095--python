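{
 "name": "AN2",
 "kind": "analyte",
 "formal_charge": -1,
 "anchor_index": null,
 "terminal_index": 11,
 "atoms": [
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": -3.807462991433713
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": -2.538308660955809
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": -1.2691543304779045
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
   "element": "C",
   "charge": 0.2,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 5.609154330477904
  },
  {
   "element": "O",
   "charge": -0.6,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": 1.0458,
   "y": 0.0,
   "z": 6.314754330477904
  },
  {
   "element": "O",
   "charge": -0.6,
   "sigma": 3.0,
   "epsilon": 0.21,
   "x": -1.0458,
   "y": 0.0,
   "z": 6.314754330477904
  }
 ],
 "bonds": [
  [
   0,
   1,
   1.54
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
   8,
   1.4
  ],
  [
   8,
   9,
   1.4
  ],
  [
   9,
   4,
   1.4
  ],
  [
   3,
   7,
   1.54
  ],
  [
   4,
   10,
   1.54
  ],
  [
   10,
   11,
   1.26
  ],
  [
   10,
   12,
   1.26
  ]
 ],
 "group_flags": {
  "4": "aromatic_carbon",
  "5": "aromatic_carbon",
  "6": "aromatic_carbon",
  "7": "aromatic_carbon",
  "8": "aromatic_carbon",
  "9": "aromatic_carbon",
  "11": "carboxylate_oxygen",
  "12": "carboxylate_oxygen"
 }
}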