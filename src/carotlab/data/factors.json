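[
  {"name": "cheese_whey", "low": 20, "center": 50, "high": 80, "units": "% v/v"},
  {"name": "peptone", "low": 0.5, "center": 1.0, "high": 1.5, "units": "g% w/v"},
  {"name": "casein", "low": 0.0, "center": 0.5, "high": 1.0, "units": "g% w/v"}
]
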