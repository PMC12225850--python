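{
 "name": "twelve_tg",
 "tg_breaks": [
  30.0,
  50.0,
  75.0,
  100.0,
  125.0,
  150.0,
  175.0,
  200.0,
  250.0,
  300.0,
  350.0
 ],
 "nonhdl_breaks_per_tg": [
  [],
  [],
  [],
  [],
  [],
  [],
  [],
  [],
  [],
  [],
  [],
  []
 ]
}
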