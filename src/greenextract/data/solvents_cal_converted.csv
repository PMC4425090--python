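name,delta_d,delta_p,delta_h,cp,t_boil,dh_vap,density,t_melt,viscosity,price
n-hexane,14.93215,0.0,0.0,2.27,69,328,0.675,-95,0.31,0.9
MeTHF,16.97765,3.88645,6.1365,1.758,80,375,0.855,-136,0.60,5.0
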