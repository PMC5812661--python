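[
  {"parameter": "T1", "day": 1, "group": "cPH", "direction": "increase", "expected": 18},
  {"parameter": "T1", "day": 1, "group": "ePH", "direction": "increase", "expected": 40},
  {"parameter": "T1", "day": 2, "group": "cPH", "direction": "increase", "expected": 24},
  {"parameter": "T1", "day": 2, "group": "ePH", "direction": "increase", "expected": 49},
  {"parameter": "T2", "day": 5, "group": "cPH", "direction": "increase", "expected": 21},
  {"parameter": "T2", "day": 5, "group": "ePH", "direction": "increase", "expected": 41},
  {"parameter": "ADC", "day": 1, "group": "cPH", "direction": "decrease", "expected": 13},
  {"parameter": "MTR", "day": 1, "group": "cPH", "direction": "decrease", "expected": 11},
  {"parameter": "MTR", "day": 1, "group": "ePH", "direction": "decrease", "expected": 15}
]
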