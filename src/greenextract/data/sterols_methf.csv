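analyte,mean,sd,n,unit,censored_limit
Cholesterol,0.40,0.00,3,%,
Brassicasterol,8.20,0.10,3,%,
24-methyl-cholesterol,1.20,0.00,3,%,
Campesterol,37.23,0.31,3,%,
Campestanol,0.13,0.12,3,%,
Stigmasterol,0.27,0.06,3,%,
d7-Campesterol,0.27,0.06,3,%,
d5.23-Stigmastadienol,0.23,0.06,3,%,
Clerosterol,0.57,0.06,3,%,
beta-sitosterol,48.30,0.26,3,%,
Sitostanol,0.20,0.00,3,%,
d5-Avenasterol,2.37,0.06,3,%,
d5.24-Stigmastadienol,0.53,0.06,3,%,
d7-Stigmasterol,,,3,%,0.1
d7-Avenasterol,,,3,%,0.1
Unidentified,,,3,%,0.1
total_sterols,810,22,3,mg/100 g,
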