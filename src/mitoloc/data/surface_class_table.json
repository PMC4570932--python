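{
 "classes": [
  {
   "class_id": "L1_Z0",
   "n_lateral": 1,
   "n_z": 0,
   "pair": ""
  },
  {
   "class_id": "L2adj_Z0",
   "n_lateral": 2,
   "n_z": 0,
   "pair": "adj"
  },
  {
   "class_id": "L2opp_Z0",
   "n_lateral": 2,
   "n_z": 0,
   "pair": "opp"
  },
  {
   "class_id": "L3_Z0",
   "n_lateral": 3,
   "n_z": 0,
   "pair": ""
  },
  {
   "class_id": "L4_Z0",
   "n_lateral": 4,
   "n_z": 0,
   "pair": ""
  },
  {
   "class_id": "L0_Z1",
   "n_lateral": 0,
   "n_z": 1,
   "pair": ""
  },
  {
   "class_id": "L1_Z1",
   "n_lateral": 1,
   "n_z": 1,
   "pair": ""
  },
  {
   "class_id": "L2_Z1",
   "n_lateral": 2,
   "n_z": 1,
   "pair": ""
  },
  {
   "class_id": "L3_Z1",
   "n_lateral": 3,
   "n_z": 1,
   "pair": ""
  },
  {
   "class_id": "L4_Z1",
   "n_lateral": 4,
   "n_z": 1,
   "pair": ""
  },
  {
   "class_id": "L0_Z2",
   "n_lateral": 0,
   "n_z": 2,
   "pair": ""
  },
  {
   "class_id": "L1_Z2",
   "n_lateral": 1,
   "n_z": 2,
   "pair": ""
  },
  {
   "class_id": "L2_Z2",
   "n_lateral": 2,
   "n_z": 2,
   "pair": ""
  },
  {
   "class_id": "L3_Z2",
   "n_lateral": 3,
   "n_z": 2,
   "pair": ""
  },
  {
   "class_id": "L4_Z2",
   "n_lateral": 4,
   "n_z": 2,
   "pair": ""
  }
 ],
 "anisotropies": [
  1.0,
  1.6,
  2.0
 ],
 "factors": {
  "L1_Z0": [
   1.0,
   1.0,
   1.0
  ],
  "L2adj_Z0": [
   0.8190950857304156,
   0.892052727177353,
   0.9042319488512276
  ],
  "L2opp_Z0": [
   0.9999999999999996,
   1.0000000000000009,
   1.0000000000000018
  ],
  "L3_Z0": [
   0.9999999999999991,
   0.9999999999999987,
   0.9999999999999993
  ],
  "L4_Z0": [
   0.9999999999999997,
   0.9999999999999996,
   0.9999999999999998
  ],
  "L0_Z1": [
   1.0,
   1.0,
   1.0
  ],
  "L1_Z1": [
   0.6439787092996644,
   0.6438233862654089,
   0.6609539260655191
  ],
  "L2_Z1": [
   0.4980592064144584,
   0.4990493877212403,
   0.4942078750502681
  ],
  "L3_Z1": [
   1.01970243860444,
   0.9835690516085537,
   1.008309146546131
  ],
  "L4_Z1": [
   0.9999999999999998,
   1.0,
   0.9999999999999996
  ],
  "L0_Z2": [
   1.0,
   0.9999999999999996,
   0.9999999999999993
  ],
  "L1_Z2": [
   1.0,
   1.0005735458274245,
   0.9948764030621033
  ],
  "L2_Z2": [
   1.007884110230831,
   1.009524517180312,
   0.9441760438658989
  ],
  "L3_Z2": [
   1.0,
   1.0,
   1.001497629507151
  ],
  "L4_Z2": [
   1.0,
   1.0,
   0.9999999999999999
  ]
 },
 "calibration": {
  "radii_vox": [
   5.0,
   6.5,
   8.0,
   10.0,
   13.0,
   16.0,
   20.0,
   26.0,
   33.0,
   40.0
  ],
  "anisotropies": [
   1.0,
   1.6,
   2.0
  ],
  "offsets": [
   [
    0.17,
    0.23,
    0.11
   ],
   [
    0.41,
    0.07,
    0.33
   ]
  ],
  "ridge": 0.3,
  "rms_rel_error": {
   "1.0": 0.01752491068047751,
   "1.6": 0.015910311521082066,
   "2.0": 0.019615445651963298
  }
 }
}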