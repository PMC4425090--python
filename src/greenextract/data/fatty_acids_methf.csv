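analyte,mean,sd,n,unit
C16,4.45,0.18,3,%
C16:1 n-7,0.27,0.02,3,%
C18,1.34,0.08,3,%
C18:1 n-9,58.28,0.83,3,%
C18:2 n-6,22.81,0.27,3,%
C18:3 n-3,9.33,0.17,3,%
C20,0.46,0.04,3,%
C20:1 n-9,1.60,0.05,3,%
C20:5 n-3,0.28,0.01,3,%
C22:1 n-9,1.68,0.06,3,%
C22:2 n-6,0.58,0.03,3,%
extraction_yield,45.96,0.80,3,g/100 g DM
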