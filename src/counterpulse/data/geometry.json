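{
 "description": "Synthetic adult aortic-arch geometry fixture (not patient CT data): per-segment centerline length and sampled lumen areas.",
 "units": {
  "length_cm": "cm",
  "areas_cm2": "cm^2"
 },
 "segments": [
  {
   "name": "asc_aorta_1",
   "parent": "root",
   "length_cm": 3.0,
   "areas_cm2": [
    6.864,
    6.9172,
    6.7394,
    6.6283,
    6.7261,
    6.6991,
    6.5015,
    6.4751,
    6.5684,
    6.4592,
    6.2892,
    6.336
   ]
  },
  {
   "name": "coronary_trunk",
   "parent": "root",
   "length_cm": 1.2,
   "areas_cm2": [
    0.1397,
    0.14,
    0.1356,
    0.1326,
    0.1337,
    0.1324,
    0.1276,
    0.1263,
    0.1273,
    0.1243,
    0.1202,
    0.1202
   ],
   "terminal": "coronaries"
  },
  {
   "name": "asc_aorta_2",
   "parent": "asc_aorta_1",
   "length_cm": 3.0,
   "areas_cm2": [
    6.552,
    6.6028,
    6.4331,
    6.327,
    6.4204,
    6.3946,
    6.2059,
    6.1807,
    6.2699,
    6.1656,
    6.0033,
    6.048
   ]
  },
  {
   "name": "brachiocephalic",
   "parent": "asc_aorta_2",
   "length_cm": 3.5,
   "areas_cm2": [
    1.643,
    1.6502,
    1.6024,
    1.5705,
    1.5881,
    1.5761,
    1.5241,
    1.5123,
    1.5283,
    1.4971,
    1.452,
    1.457
   ]
  },
  {
   "name": "right_subclavian",
   "parent": "brachiocephalic",
   "length_cm": 3.5,
   "areas_cm2": [
    0.6572,
    0.6601,
    0.641,
    0.6282,
    0.6353,
    0.6304,
    0.6096,
    0.6049,
    0.6113,
    0.5988,
    0.5808,
    0.5828
   ],
   "terminal": "right_subclavian"
  },
  {
   "name": "right_carotid",
   "parent": "brachiocephalic",
   "length_cm": 3.5,
   "areas_cm2": [
    0.4664,
    0.4685,
    0.4549,
    0.4458,
    0.4508,
    0.4474,
    0.4326,
    0.4293,
    0.4338,
    0.425,
    0.4122,
    0.4136
   ],
   "terminal": "right_carotid"
  },
  {
   "name": "arch_1",
   "parent": "asc_aorta_2",
   "length_cm": 2.5,
   "areas_cm2": [
    5.824,
    5.8691,
    5.7183,
    5.624,
    5.707,
    5.6841,
    5.5164,
    5.494,
    5.5732,
    5.4805,
    5.3363,
    5.376
   ]
  },
  {
   "name": "left_carotid",
   "parent": "arch_1",
   "length_cm": 3.5,
   "areas_cm2": [
    0.4664,
    0.4685,
    0.4549,
    0.4458,
    0.4508,
    0.4474,
    0.4326,
    0.4293,
    0.4338,
    0.425,
    0.4122,
    0.4136
   ],
   "terminal": "left_carotid"
  },
  {
   "name": "arch_2",
   "parent": "arch_1",
   "length_cm": 2.5,
   "areas_cm2": [
    5.304,
    5.3451,
    5.2077,
    5.1219,
    5.1974,
    5.1766,
    5.0238,
    5.0035,
    5.0756,
    4.9912,
    4.8598,
    4.896
   ]
  },
  {
   "name": "left_subclavian",
   "parent": "arch_2",
   "length_cm": 3.8,
   "areas_cm2": [
    0.6996,
    0.7027,
    0.6823,
    0.6687,
    0.6762,
    0.6711,
    0.649,
    0.6439,
    0.6508,
    0.6375,
    0.6183,
    0.6204
   ],
   "terminal": "left_subclavian"
  },
  {
   "name": "desc_aorta",
   "parent": "arch_2",
   "length_cm": 20.0,
   "areas_cm2": [
    4.3875,
    4.3627,
    4.1924,
    4.0654,
    4.0657,
    3.989,
    3.812,
    3.7365,
    3.7286,
    3.6049,
    3.4492,
    3.4125
   ],
   "terminal": "descending_aorta"
  }
 ]
}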