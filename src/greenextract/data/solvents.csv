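name,delta_d,delta_p,delta_h,cp,t_boil,dh_vap,density,t_melt,viscosity,price
n-hexane,14.0,0.0,0.0,2.27,69,328,0.675,-95,0.31,0.9
MeTHF,16.4,4.7,4.6,1.758,80,375,0.855,-136,0.60,5.0
d-limonene,16.7,1.8,3.1,,176,,0.841,-74,,
p-cymene,17.3,2.3,2.4,,177,,0.857,-68,,
methyl acetate,15.5,7.2,7.6,,57,,0.932,-98,,
ethyl acetate,15.8,5.3,7.2,,77,,0.902,-84,,
butanol,16.0,5.7,15.8,,118,,0.810,-90,,
IPA,15.8,6.1,16.4,,82,,0.786,-89,,
ethanol,15.8,8.8,19.4,,78,,0.789,-114,,
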