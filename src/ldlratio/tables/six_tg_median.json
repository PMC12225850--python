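{
 "scheme": {
  "name": "six_tg",
  "tg_breaks": [
   50.0,
   100.0,
   150.0,
   200.0,
   300.0
  ],
  "nonhdl_breaks_per_tg": [
   [],
   [],
   [],
   [],
   [],
   []
  ]
 },
 "statistic": "median",
 "cells": [
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "3.1",
   "n": 1140,
   "ci_lo": 2.98,
   "ci_hi": 3.19,
   "acl": 0.953,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "4.4",
   "n": 4648,
   "ci_lo": 4.39,
   "ci_hi": 4.49,
   "acl": 0.952,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "5.4",
   "n": 3127,
   "ci_lo": 5.36,
   "ci_hi": 5.49,
   "acl": 0.951,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "5.9",
   "n": 1523,
   "ci_lo": 5.76,
   "ci_hi": 5.95,
   "acl": 0.954,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "6.2",
   "n": 6132,
   "ci_lo": 6.15,
   "ci_hi": 6.25,
   "acl": 0.952,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "6.4",
   "n": 1752,
   "ci_lo": 6.36,
   "ci_hi": 6.52,
   "acl": 0.953,
   "tie": false
  }
 ]
}
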