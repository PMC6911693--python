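{
 "version": "1.0",
 "description": "Simplified nearest-neighbor stacking model: stack energy of two adjacent nested pairs is -(strength(outer)+strength(inner)); hairpin loops (>=3 unpaired) cost +hairpin_penalty; all other loops and unpaired bases contribute 0. Units are kcal/mol-like model units.",
 "pair_strengths": {
  "GC": 1.65,
  "CG": 1.65,
  "AU": 0.55,
  "UA": 0.55,
  "GU": 0.25,
  "UG": 0.25
 },
 "hairpin_penalty": 4.0
}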