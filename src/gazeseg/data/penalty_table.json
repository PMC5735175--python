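{
 "axes": {
  "a_star": [
   2.5,
   5.0,
   10.0,
   20.0
  ],
  "d_star": [
   0.25,
   0.5,
   1.0,
   2.0
  ],
  "v_star": [
   0.0,
   5.0,
   10.0,
   20.0
  ],
  "out_rate": [
   60.0,
   250.0,
   500.0,
   1000.0
  ]
 },
 "penalty": [
  [
   [
    [
     2.23606797749979,
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     0.5,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.5,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.8237744862210329,
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172
    ]
   ],
   [
    [
     1.3572088082974534,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     3.6840314986403864,
     10.0,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     6.069622310029172,
     3.6840314986403864,
     10.0,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     10.0
    ],
    [
     2.23606797749979,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172
    ]
   ],
   [
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     16.475489724420658
    ],
    [
     6.069622310029172,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     10.0,
     10.0
    ]
   ]
  ],
  [
   [
    [
     0.5,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.5,
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     0.5,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.8237744862210329,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     1.3572088082974534,
     3.6840314986403864,
     6.069622310029172,
     10.0
    ],
    [
     0.8237744862210329,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     2.23606797749979,
     6.069622310029172,
     6.069622310029172,
     10.0
    ],
    [
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     10.0,
     10.0
    ]
   ],
   [
    [
     3.6840314986403864,
     6.069622310029172,
     10.0,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     10.0,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     10.0,
     6.069622310029172,
     6.069622310029172
    ],
    [
     6.069622310029172,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ]
   ]
  ],
  [
   [
    [
     0.8237744862210329,
     3.6840314986403864,
     6.069622310029172,
     3.6840314986403864
    ],
    [
     6.069622310029172,
     6.069622310029172,
     3.6840314986403864,
     3.6840314986403864
    ],
    [
     0.8237744862210329,
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     0.5,
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172
    ]
   ],
   [
    [
     1.3572088082974534,
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     0.5,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     2.23606797749979,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     2.23606797749979,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     6.069622310029172,
     10.0,
     6.069622310029172,
     6.069622310029172
    ],
    [
     6.069622310029172,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     10.0,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     6.069622310029172,
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     6.069622310029172,
     6.069622310029172,
     10.0,
     6.069622310029172
    ],
    [
     6.069622310029172,
     6.069622310029172,
     10.0,
     10.0
    ]
   ]
  ],
  [
   [
    [
     0.5,
     3.6840314986403864,
     6.069622310029172,
     3.6840314986403864
    ],
    [
     2.23606797749979,
     2.23606797749979,
     3.6840314986403864,
     3.6840314986403864
    ],
    [
     0.8237744862210329,
     3.6840314986403864,
     3.6840314986403864,
     3.6840314986403864
    ],
    [
     1.3572088082974534,
     3.6840314986403864,
     3.6840314986403864,
     3.6840314986403864
    ]
   ],
   [
    [
     3.6840314986403864,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.8237744862210329,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ],
    [
     1.3572088082974534,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     2.23606797749979,
     6.069622310029172,
     3.6840314986403864,
     3.6840314986403864
    ]
   ],
   [
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     1.3572088082974534,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     0.5,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     6.069622310029172,
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172
    ]
   ],
   [
    [
     3.6840314986403864,
     6.069622310029172,
     10.0,
     6.069622310029172
    ],
    [
     10.0,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ],
    [
     3.6840314986403864,
     6.069622310029172,
     6.069622310029172,
     10.0
    ],
    [
     6.069622310029172,
     6.069622310029172,
     6.069622310029172,
     6.069622310029172
    ]
   ]
  ]
 ],
 "meta": {
  "base_seed": 2024,
  "n_reps": 3,
  "duration_s": 10.0,
  "calibration_sigma_deg": 0.5,
  "penalty_grid": [
   0.5,
   0.8237744862210329,
   1.3572088082974534,
   2.23606797749979,
   3.6840314986403864,
   6.069622310029172,
   10.0,
   16.475489724420658,
   27.144176165949066,
   44.721359549995796,
   73.68062997280774,
   121.39244620058346,
   200.0
  ],
  "objective": "mean squared reconstruction error vs noiseless truth"
 }
}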