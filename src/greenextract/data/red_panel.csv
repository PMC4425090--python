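solvent,solute,red
n-hexane,TAG1,1.12
MeTHF,TAG1,0.83
d-limonene,TAG1,0.15
p-cymene,TAG1,0.49
methyl acetate,TAG1,1.83
ethyl acetate,TAG1,1.40
butanol,TAG1,3.35
IPA,TAG1,3.53
ethanol,TAG1,4.47
n-hexane,TAG2,1.10
MeTHF,TAG2,0.92
d-limonene,TAG2,0.16
p-cymene,TAG2,0.38
methyl acetate,TAG2,1.95
ethyl acetate,TAG2,1.53
butanol,TAG2,3.49
IPA,TAG2,3.67
ethanol,TAG2,4.66
n-hexane,TAG3,1.06
MeTHF,TAG3,0.97
d-limonene,TAG3,0.21
p-cymene,TAG3,0.39
methyl acetate,TAG3,2.00
ethyl acetate,TAG3,1.59
butanol,TAG3,3.54
IPA,TAG3,3.72
ethanol,TAG3,4.60
n-hexane,TAG4,1.09
MeTHF,TAG4,0.89
d-limonene,TAG4,0.14
p-cymene,TAG4,0.43
methyl acetate,TAG4,1.91
ethyl acetate,TAG4,1.48
butanol,TAG4,3.43
IPA,TAG4,3.61
ethanol,TAG4,4.55
n-hexane,PE,2.96
MeTHF,PE,1.32
d-limonene,PE,2.00
p-cymene,PE,2.13
methyl acetate,PE,0.67
ethyl acetate,PE,0.71
butanol,PE,1.57
IPA,PE,1.72
ethanol,PE,2.53
n-hexane,PC,2.74
MeTHF,PC,1.23
d-limonene,PC,1.80
p-cymene,PC,1.97
methyl acetate,PC,0.82
ethyl acetate,PC,0.62
butanol,PC,1.59
IPA,PC,1.76
ethanol,PC,2.67
n-hexane,LPC,3.67
MeTHF,LPC,2.09
d-limonene,LPC,2.71
p-cymene,LPC,2.83
methyl acetate,LPC,1.26
ethyl acetate,LPC,1.42
butanol,LPC,1.00
IPA,LPC,1.12
ethanol,LPC,1.83
n-hexane,T1,1.09
MeTHF,T1,1.06
d-limonene,T1,0.24
p-cymene,T1,0.50
methyl acetate,T1,2.06
ethyl acetate,T1,1.61
butanol,T1,3.48
IPA,T1,3.66
ethanol,T1,4.61
n-hexane,T2,1.40
MeTHF,T2,0.82
d-limonene,T2,0.23
p-cymene,T2,0.18
methyl acetate,T2,1.88
ethyl acetate,T2,1.46
butanol,T2,3.36
IPA,T2,3.55
ethanol,T2,4.47
n-hexane,S1,1.43
MeTHF,S1,0.90
d-limonene,S1,0.25
p-cymene,S1,0.24
methyl acetate,S1,1.94
ethyl acetate,S1,1.50
butanol,S1,3.35
IPA,S1,3.54
ethanol,S1,4.47
n-hexane,S2,1.36
MeTHF,S2,0.92
d-limonene,S2,0.20
p-cymene,S2,0.23
methyl acetate,S2,1.96
ethyl acetate,S2,1.53
butanol,S2,3.40
IPA,S2,3.59
ethanol,S2,4.51
n-hexane,S3,1.56
MeTHF,S3,0.99
d-limonene,S3,0.40
p-cymene,S3,0.29
methyl acetate,S3,2.01
ethyl acetate,S3,1.58
butanol,S3,3.37
IPA,S3,3.56
ethanol,S3,4.48
n-hexane,W,0.81
MeTHF,W,1.15
d-limonene,W,0.44
p-cymene,W,0.65
methyl acetate,W,2.13
ethyl acetate,W,1.72
butanol,W,3.67
IPA,W,3.85
ethanol,W,4.79
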