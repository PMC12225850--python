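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
 "statistic": "optimal",
 "cells": [
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "3.9",
   "n": 949,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 0.0,
   "tg_hi": 50.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "2.9",
   "n": 191,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "4.8",
   "n": 2945,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 50.0,
   "tg_hi": 100.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "4.5",
   "n": 1703,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "6.1",
   "n": 1211,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 100.0,
   "tg_hi": 150.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "5.2",
   "n": 1916,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "6.4",
   "n": 400,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 150.0,
   "tg_hi": 200.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "5.9",
   "n": 1123,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "6.8",
   "n": 1217,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 200.0,
   "tg_hi": 300.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "6.1",
   "n": 4915,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": null,
   "nonhdl_hi": 130.0,
   "af": "8.0",
   "n": 221,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  },
  {
   "tg_lo": 300.0,
   "tg_hi": 400.0,
   "nonhdl_lo": 130.0,
   "nonhdl_hi": null,
   "af": "6.4",
   "n": 1531,
   "ci_lo": null,
   "ci_hi": null,
   "acl": null,
   "tie": false
  }
 ]
}
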