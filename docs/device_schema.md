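# Device descriptor schema

A device descriptor is a JSON object describing how an acquisition
device multiplexes its sample stream. Validation is strict on required
fields and lenient on extras (unknown keys are ignored with a logged
warning).

## Required fields

| key          | type    | meaning                                      |
|--------------|---------|----------------------------------------------|
| `name`       | string  | device/montage name, e.g. `"NIRx NIRSport2 (26CH)"` |
| `type`       | string  | `"NIRS"` or `"EEG"`                          |
| `channels`   | integer | number of measurement channels N (≥ 1)       |
| `wavelengths`| array   | nm values, **required for NIRS** (e.g. `[760, 850]`) |

## Optional fields

* `units` — object with `raw` (default `"V"`) and `chromophore`
  (default `"μmol/L"`).
* `columns` — explicit column list; when absent, the default dialect is
  constructed.

## Default NIRS dialect

For a two-wavelength NIRS descriptor without an explicit `columns` list,
the stream has `4·N + 1` columns in this order:

1. frame counter
2. N raw intensities at wavelength 1
3. N raw intensities at wavelength 2
4. N HbO concentration changes
5. N HbR concentration changes

## Explicit column lists

Each entry of `columns` is an object:

```json
{"role": "raw_intensity", "channel": 3, "wavelength": 760, "unit": "V"}
```

* `role` — one of `frame_counter`, `raw_intensity`, `hbo`, `hbr`
* `channel` — 1-based channel ID (absent only for `frame_counter`)
* `wavelength` — nm, required for `raw_intensity`
* `unit` — free-form string

`(role, wavelength, channel)` must be unique; channel IDs must not exceed
`channels`; for NIRS the total column count must equal
`2 · len(wavelengths) · channels + 1`. Any column order the JSON declares
is legal — the default dialect above is a convention, not a constraint.

Template descriptors ship with the package under `nirsfeed/devices/`
(`nirs_generic.json`, `eeg_generic.json`).
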