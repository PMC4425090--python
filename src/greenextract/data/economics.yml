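# Default substitution assumptions, EUR basis.
solvent_price_alt: 5.0        # EUR/kg
solvent_price_ref: 0.9
solvent_consumption: 0.75     # kg per t of seeds
extra_steam: 37.0             # kg per t of seeds
steam_price: 30.0             # EUR/t
extra_oil_gross: 10.0         # kg per t of seeds
oil_recovery_value_fraction: 0.60
oil_price: 900.0
cake_price: 350.0
capacity_gain_fraction: 0.05
fixed_cost_reduction: 0.8
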