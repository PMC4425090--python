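analyte,mean,sd,n,unit
C16,4.44,0.23,3,%
C16:1 n-7,0.24,0.01,3,%
C18,1.37,0.07,3,%
C18:1 n-9,58.26,0.88,3,%
C18:2 n-6,22.59,0.32,3,%
C18:3 n-3,9.43,0.13,3,%
C20,0.45,0.01,3,%
C20:1 n-9,1.64,0.09,3,%
C20:5 n-3,0.22,0.01,3,%
C22:1 n-9,0.22,0.01,3,%
C22:2 n-6,0.22,0.01,3,%
extraction_yield,46.34,0.48,3,g/100 g DM
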