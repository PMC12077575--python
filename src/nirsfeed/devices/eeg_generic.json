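{
  "name": "Generic EEG (32CH)",
  "type": "EEG",
  "channels": 32,
  "units": {"raw": "μV"}
}
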