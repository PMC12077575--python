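{
  "name": "Generic NIRS (26CH)",
  "type": "NIRS",
  "channels": 26,
  "wavelengths": [760, 850],
  "units": {"raw": "V", "chromophore": "μmol/L"}
}
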