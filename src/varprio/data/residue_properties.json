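{
  "_scales": {
    "volume": "Zamyatnin (1972) mean residue volumes, cubic Angstrom",
    "hydropathy": "Kyte & Doolittle (1982) hydropathy index",
    "charge_class": "net side-chain charge at physiological pH (His neutral)"
  },
  "Ala": {"volume": 88.6,  "hydropathy": 1.8,  "charge_class": "neutral"},
  "Arg": {"volume": 173.4, "hydropathy": -4.5, "charge_class": "positive"},
  "Asn": {"volume": 114.1, "hydropathy": -3.5, "charge_class": "neutral"},
  "Asp": {"volume": 111.1, "hydropathy": -3.5, "charge_class": "negative"},
  "Cys": {"volume": 108.5, "hydropathy": 2.5,  "charge_class": "neutral"},
  "Gln": {"volume": 143.8, "hydropathy": -3.5, "charge_class": "neutral"},
  "Glu": {"volume": 138.4, "hydropathy": -3.5, "charge_class": "negative"},
  "Gly": {"volume": 60.1,  "hydropathy": -0.4, "charge_class": "neutral"},
  "His": {"volume": 153.2, "hydropathy": -3.2, "charge_class": "neutral"},
  "Ile": {"volume": 166.7, "hydropathy": 4.5,  "charge_class": "neutral"},
  "Leu": {"volume": 166.7, "hydropathy": 3.8,  "charge_class": "neutral"},
  "Lys": {"volume": 168.6, "hydropathy": -3.9, "charge_class": "positive"},
  "Met": {"volume": 162.9, "hydropathy": 1.9,  "charge_class": "neutral"},
  "Phe": {"volume": 189.9, "hydropathy": 2.8,  "charge_class": "neutral"},
  "Pro": {"volume": 112.7, "hydropathy": -1.6, "charge_class": "neutral"},
  "Ser": {"volume": 89.0,  "hydropathy": -0.8, "charge_class": "neutral"},
  "Thr": {"volume": 116.1, "hydropathy": -0.7, "charge_class": "neutral"},
  "Trp": {"volume": 227.8, "hydropathy": -0.9, "charge_class": "neutral"},
  "Tyr": {"volume": 193.6, "hydropathy": -1.3, "charge_class": "neutral"},
  "Val": {"volume": 140.0, "hydropathy": 4.2,  "charge_class": "neutral"}
}
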