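{
 "scheme": {
  "name": "twelve_combined",
  "tg_breaks": [
   50.0,
   100.0,
   150.0,
   200.0,
   300.0
  ],
  "nonhdl_breaks_per_tg": [
   [
    130.0
   ],
   [
    130.0
   ],
   [
    130.0
   ],
   [
    130.0
   ],
   [
    130.0
   ],
   [
    130.0
   ]
  ]
 },
 "statistic": "median",
 "cells": [
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "3.2",
   "n": 949,
   "ci_lo": 3.07,
   "ci_hi": 3.29,
   "acl": 0.956,
   "tie": false
  },
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "2.7",
   "n": 191,
   "ci_lo": 2.58,
   "ci_hi": 2.89,
   "acl": 0.958,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "4.6",
   "n": 2945,
   "ci_lo": 4.48,
   "ci_hi": 4.64,
   "acl": 0.953,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "4.2",
   "n": 1703,
   "ci_lo": 4.15,
   "ci_hi": 4.32,
   "acl": 0.953,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "5.8",
   "n": 1211,
   "ci_lo": 5.63,
   "ci_hi": 5.84,
   "acl": 0.956,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "5.2",
   "n": 1916,
   "ci_lo": 5.1,
   "ci_hi": 5.26,
   "acl": 0.953,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "6.4",
   "n": 400,
   "ci_lo": 6.26,
   "ci_hi": 6.6,
   "acl": 0.95,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "5.7",
   "n": 1123,
   "ci_lo": 5.58,
   "ci_hi": 5.78,
   "acl": 0.951,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "6.9",
   "n": 1217,
   "ci_lo": 6.85,
   "ci_hi": 7.05,
   "acl": 0.955,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "6.0",
   "n": 4915,
   "ci_lo": 5.99,
   "ci_hi": 6.07,
   "acl": 0.951,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "7.3",
   "n": 221,
   "ci_lo": 7.09,
   "ci_hi": 7.44,
   "acl": 0.957,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "6.3",
   "n": 1531,
   "ci_lo": 6.22,
   "ci_hi": 6.38,
   "acl": 0.954,
   "tie": false
  }
 ]
}
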