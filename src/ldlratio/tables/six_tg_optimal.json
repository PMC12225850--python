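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
 "statistic": "optimal",
 "cells": [
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "3.2",
   "n": 1140,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "4.6",
   "n": 4648,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "5.6",
   "n": 3127,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "5.9",
   "n": 1523,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "6.3",
   "n": 6132,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": null,
   "nonhdl_hi": null,
   "af": "6.4",
   "n": 1752,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  }
 ]
}
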