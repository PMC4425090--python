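analyte,mean,sd,n,unit,censored_limit
Cholesterol,0.33,0.06,3,%,
Brassicasterol,8.03,0.06,3,%,
24-methyl-cholesterol,1.23,0.12,3,%,
Campesterol,37.47,0.06,3,%,
Campestanol,0.10,0.00,3,%,
Stigmasterol,0.20,0.00,3,%,
d7-Campesterol,0.27,0.06,3,%,
d5.23-Stigmastadienol,0.23,0.06,3,%,
Clerosterol,0.60,0.00,3,%,
beta-sitosterol,48.30,0.30,3,%,
Sitostanol,0.20,0.00,3,%,
d5-Avenasterol,2.20,0.10,3,%,
d5.24-Stigmastadienol,0.50,0.00,3,%,
d7-Stigmasterol,0.10,0.00,3,%,
d7-Avenasterol,0.25,0.21,3,%,
Unidentified,,,3,%,0.1
total_sterols,881,14,3,mg/100 g,
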