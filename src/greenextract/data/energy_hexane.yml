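# Crushing-process scenario, hexane route. Basis: 1 tonne of seeds.
solvent: n-hexane
sparged_steam_ratio: 0.12      # kg steam per kg solvent stripped
retained_solvent: 228.7        # kg/t held by the dry matter entering the DT
retained_mode: mass
oil_to_distillation: 122.9     # kg/t (back-solved from the distillation balance)
miscella_heating_heat: 8.0     # MJ/t, fixed (irreconcilable with mass*cp)
meal_mass: 550.0
meal_cp: 1.9
oil_cp: 2.0
extraction_t: 55.0
desolventizer_exit_t: 105.0
oil_final_t: 110.0
miscella_oil_fraction: 0.25
condensed_steam_heat: 38.0
heat_recovery_fraction: 0.75
loss_fraction: 0.05
steam:
  latent_heat_6bar: 2085.0
  latent_heat_10bar: 2000.0
  total_enthalpy_sparged: 2778.0
  price_eur_t: 30.0
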