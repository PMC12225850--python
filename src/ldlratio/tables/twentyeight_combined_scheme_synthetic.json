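{
 "name": "twentyeight_combined",
 "tg_breaks": [
  50.0,
  100.0,
  150.0,
  200.0,
  300.0
 ],
 "nonhdl_breaks_per_tg": [
  [
   130.0,
   190.0
  ],
  [
   100.0,
   130.0,
   160.0,
   190.0
  ],
  [
   100.0,
   130.0,
   160.0,
   190.0
  ],
  [
   100.0,
   130.0,
   160.0,
   190.0
  ],
  [
   100.0,
   130.0,
   160.0,
   190.0
  ],
  [
   100.0,
   130.0,
   160.0,
   190.0
  ]
 ]
}
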