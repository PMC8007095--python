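{
 "name": "A3",
 "kind": "analyte",
 "formal_charge": 1,
 "anchor_index": null,
 "terminal_index": 4,
 "atoms": [
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": -2.5383086609558085
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.8722656048642425,
   "y": 0.0,
   "z": -1.2691543304779043
  },
  {
   "element": "C",
   "charge": 0.0,
   "sigma": 3.4,
   "epsilon": 0.09,
   "x": 0.0,
   "y": 0.0,
   "z": 0.0
  },
  {
   "element": "N",
   "charge": 0.25,
   "sigma": 3.25,
   "epsilon": 0.17,
   "x": 0.0,
   "y": 0.0,
   "z": 1.48
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": 0.9364556931124554,
   "y": 0.0,
   "z": 1.858352659350071
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": -0.46822784655622746,
   "y": 0.8109944197539505,
   "z": 1.858352659350071
  },
  {
   "element": "H",
   "charge": 0.25,
   "sigma": 1.069,
   "epsilon": 0.0157,
   "x": -0.46822784655622807,
   "y": -0.8109944197539501,
   "z": 1.858352659350071
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
   1.48
  ],
  [
   3,
   4,
   1.01
  ],
  [
   3,
   5,
   1.01
  ],
  [
   3,
   6,
   1.01
  ]
 ],
 "group_flags": {
  "3": "ammonium_nitrogen"
 }
}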