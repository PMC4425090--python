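# Washing-stage simulation defaults: 5 washes of 30 min, 1.5 kg solvent per
# kg of cake. The particle radius is calibrated against the pilot recovery
# pattern (~96% after five hexane washes, ~95% after three MeTHF washes).
n_washes: 5
wash_duration_min: 30.0
solvent_to_solid: 1.5
retention: 0.3               # kg miscella per kg dry matter
retention_mode: mass
rd: 0.45e-3                  # m, calibrated
oil_content_initial: 0.21    # g/g DM (press cake)
deff_ref: 0.034e-10          # m2/s, hexane
deff_alt: 0.122e-10          # m2/s, MeTHF
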