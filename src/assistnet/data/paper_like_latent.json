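{
 "substances": [
  "tobacco",
  "alcohol",
  "cannabis",
  "cocaine",
  "ats",
  "inhalants",
  "sedatives",
  "hallucinogens",
  "opioids",
  "other"
 ],
 "latent_correlation": [
  [
   1.0,
   0.613977,
   0.802547,
   0.60822,
   0.759456,
   0.553449,
   0.427756,
   0.648116,
   0.576492,
   0.457106
  ],
  [
   0.613977,
   1.0,
   0.496344,
   0.525191,
   0.637585,
   0.479187,
   0.354069,
   0.5297,
   0.498289,
   0.392841
  ],
  [
   0.802547,
   0.496344,
   1.0,
   0.616417,
   0.800469,
   0.549833,
   0.44673,
   0.70165,
   0.578544,
   0.465756
  ],
  [
   0.60822,
   0.525191,
   0.616417,
   1.0,
   0.744717,
   0.474264,
   0.45754,
   0.55699,
   0.516002,
   0.43098
  ],
  [
   0.759456,
   0.637585,
   0.800469,
   0.744717,
   1.0,
   0.628986,
   0.614934,
   0.775938,
   0.699012,
   0.575774
  ],
  [
   0.553449,
   0.479187,
   0.549833,
   0.474264,
   0.628986,
   1.0,
   0.40802,
   0.493625,
   0.459789,
   0.390459
  ],
  [
   0.427756,
   0.354069,
   0.44673,
   0.45754,
   0.614934,
   0.40802,
   1.0,
   0.470651,
   0.64401,
   0.372801
  ],
  [
   0.648116,
   0.5297,
   0.70165,
   0.55699,
   0.775938,
   0.493625,
   0.470651,
   1.0,
   0.535891,
   0.448694
  ],
  [
   0.576492,
   0.498289,
   0.578544,
   0.516002,
   0.699012,
   0.459789,
   0.64401,
   0.535891,
   1.0,
   0.426526
  ],
  [
   0.457106,
   0.392841,
   0.465756,
   0.43098,
   0.575774,
   0.390459,
   0.372801,
   0.448694,
   0.426526,
   1.0
  ]
 ],
 "target_score_partials": [
  [
   0.0,
   0.28,
   0.48,
   0.03,
   0.06,
   0.03,
   0.03,
   0.03,
   0.03,
   0.03
  ],
  [
   0.28,
   0.0,
   0.03,
   0.03,
   0.05,
   0.03,
   0.03,
   0.03,
   0.03,
   0.03
  ],
  [
   0.48,
   0.03,
   0.0,
   0.03,
   0.18,
   0.03,
   0.03,
   0.1,
   0.03,
   0.03
  ],
  [
   0.03,
   0.03,
   0.03,
   0.0,
   0.26,
   0.03,
   0.03,
   0.03,
   0.03,
   0.03
  ],
  [
   0.06,
   0.05,
   0.18,
   0.26,
   0.0,
   0.13,
   0.15,
   0.3,
   0.18,
   0.13
  ],
  [
   0.03,
   0.03,
   0.03,
   0.03,
   0.13,
   0.0,
   0.03,
   0.03,
   0.03,
   0.03
  ],
  [
   0.03,
   0.03,
   0.03,
   0.03,
   0.15,
   0.03,
   0.0,
   0.03,
   0.21,
   0.03
  ],
  [
   0.03,
   0.03,
   0.1,
   0.03,
   0.3,
   0.03,
   0.03,
   0.0,
   0.03,
   0.03
  ],
  [
   0.03,
   0.03,
   0.03,
   0.03,
   0.18,
   0.03,
   0.21,
   0.03,
   0.0,
   0.03
  ],
  [
   0.03,
   0.03,
   0.03,
   0.03,
   0.13,
   0.03,
   0.03,
   0.03,
   0.03,
   0.0
  ]
 ],
 "achieved_score_partials": [
  [
   0.0,
   0.2841,
   0.4834,
   0.0304,
   0.061,
   0.0272,
   0.0346,
   0.0269,
   0.0311,
   0.0277
  ],
  [
   0.2841,
   0.0,
   0.0446,
   0.0253,
   0.039,
   0.0229,
   0.0457,
   0.0274,
   0.0221,
   0.0351
  ],
  [
   0.4834,
   0.0446,
   0.0,
   0.0307,
   0.1711,
   0.0262,
   0.0379,
   0.101,
   0.0214,
   0.0349
  ],
  [
   0.0304,
   0.0253,
   0.0307,
   0.0,
   0.2592,
   0.0331,
   0.0261,
   0.0349,
   0.0327,
   0.0239
  ],
  [
   0.061,
   0.039,
   0.1711,
   0.2592,
   0.0,
   0.1308,
   0.1442,
   0.3012,
   0.1828,
   0.1334
  ],
  [
   0.0272,
   0.0229,
   0.0262,
   0.0331,
   0.1308,
   0.0,
   0.0273,
   0.0391,
   0.0348,
   0.0263
  ],
  [
   0.0346,
   0.0457,
   0.0379,
   0.0261,
   0.1442,
   0.0273,
   0.0,
   0.0268,
   0.202,
   0.0342
  ],
  [
   0.0269,
   0.0274,
   0.101,
   0.0349,
   0.3012,
   0.0391,
   0.0268,
   0.0,
   0.0302,
   0.0284
  ],
  [
   0.0311,
   0.0221,
   0.0214,
   0.0327,
   0.1828,
   0.0348,
   0.202,
   0.0302,
   0.0,
   0.0341
  ],
  [
   0.0277,
   0.0351,
   0.0349,
   0.0239,
   0.1334,
   0.0263,
   0.0342,
   0.0284,
   0.0341,
   0.0
  ]
 ],
 "expected_mean_rt": 0.4419,
 "calibration": {
  "n_sim": 400000,
  "n_iter": 14,
  "seed": 20260927
 }
}
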