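{
  "boundary_window": 5,
  "domains": [
    {"name": "BRC repeats", "start": 1003, "end": 2082, "critical": true},
    {"name": "DNA-binding domain", "start": 2804, "end": 3054, "critical": true},
    {"name": "terminal DBD", "start": 3052, "end": 3185, "critical": true},
    {"name": "C-terminal region", "start": 3190, "end": 3418, "critical": false}
  ]
}
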