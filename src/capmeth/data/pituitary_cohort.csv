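patient_id,group,sex,high_risk_area,age,macro,dmax_mm,cavernous_invasion,ki67_pct,p53_pct,n_surgeries,aip_mutation
GH1,GH,F,,27,Macro,22,No,2,0,1,
GH2,GH,F,Yes,76,Macro,15,No,1,0,1,
GH3,GH,F,,46,Macro,10,No,2,<1,1,
GH4,GH,M,,NA,Macro,NA,No,NA,NA,1,
GH5,GH,M,,57,Macro,22.5,No,1,,1,
GH7,GH,F,,48,Macro,11,No,1,2,1,
GH8,GH,F,,28,Macro,18,,5,2,1,
GH9,GH,F,,22,Micro,5,No,<1,,1,Yes
GH10,GH,F,,35,Macro,12,No,<1,0,1,
GH11,GH,M,Yes,63,Macro,43,Yes,5,0,2,
GH12,GH,M,,57,Macro,11,Yes,<1,0,1,
NFPA1,NFPA,F,,46,Macro,30,Yes,3,1,1,
NFPA5,NFPA,F,,46,Macro,22,No,<1,,1,
NFPA6,NFPA,M,,42,Macro,30,No,NA,NA,1,
NFPA8,NFPA,F,,NA,Macro,NA,No,NA,NA,1,
NFPA11,NFPA,F,Yes,55,Macro,15,No,2,,1,
NFPA13,NFPA,M,,68,Macro,30,No,2,<1,1,
NFPA14,NFPA,F,,70,Macro,25,No,<1,,1,
NFPA16,NFPA,M,,72,Macro,23,Yes,<1,,1,
NFPA18,NFPA,M,,40,Macro,34,Yes,1,,2,
NFPA19,NFPA,F,,36,Macro,30,Yes,1,3,3,
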