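# Crushing-process scenario, MeTHF route. Basis: 1 tonne of seeds.
solvent: MeTHF
sparged_steam_ratio: 0.14
retained_solvent: 288.0
retained_mode: mass
oil_to_distillation: 124.0
miscella_heating_heat: 22.0
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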