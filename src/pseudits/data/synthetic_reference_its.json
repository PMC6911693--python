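{
 "its1": [
  0,
  220
 ],
 "r58s": [
  220,
  380
 ],
 "its2": [
  380,
  611
 ],
 "note": "synthetic stand-in reference, generated by pseudits.synthetic_data.simulate_ancestors(seed=0)"
}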