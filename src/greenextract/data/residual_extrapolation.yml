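# Industrial residual-oil extrapolation inputs.
industry_residual_kg_per_t: 16.5   # 3.1% oil in 550 kg meal per t of seeds
pilot_residual_ref_pct: 1.8        # hexane pilot meal residual
pilot_residual_alt_pct: 0.8        # MeTHF pilot meal residual
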