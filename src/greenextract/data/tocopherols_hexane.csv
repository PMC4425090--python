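analyte,mean,sd,n,unit,censored_limit
tocopherol_acetate,,,3,mg/kg fat,5
alpha_tocopherol,292,10,3,mg/kg fat,
beta_tocopherol,3.3,0.6,3,mg/kg fat,
gamma_tocopherol,488,10,3,mg/kg fat,
delta_tocopherol,14.3,0.58,3,mg/kg fat,
alpha_tocotrienol,,,3,mg/kg fat,2
beta_tocotrienol,,,3,mg/kg fat,2
gamma_tocotrienol,,,3,mg/kg fat,2
delta_tocotrienol,,,3,mg/kg fat,2
total,797,119,3,mg/kg fat,
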