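patient_id,ND_HF,ERM_DR,DME_HF,DME_HF_ND,DME_ND,CNV_DR,HF,HEMORRHAGE_DR,ARTIFACT,HEALTHY
A01,0,0,5,0,0,0,13,0,0,4
B02,0,0,7,0,0,6,5,0,0,3
B03,0,7,8,0,0,0,4,3,0,0
B04,0,0,8,6,0,0,8,0,0,0
C05,0,0,9,6,7,0,0,0,0,0
C06,0,0,240,6,0,0,141,0,0,13
C07,0,0,10,0,0,0,0,0,0,0
D08,0,0,14,0,0,1,2,0,0,5
F09,0,5,0,0,6,0,1,0,0,10
F10,0,0,50,5,21,0,1,0,0,0
F11,0,0,13,50,0,0,3,0,0,0
H12,0,0,6,0,0,0,12,0,0,4
HCF1,0,0,0,0,0,0,0,0,0,31
HCF10,0,0,0,0,0,0,0,0,0,15
HCF11,0,0,0,0,0,0,0,0,0,21
HCF2,0,0,0,0,0,0,0,0,0,31
HCF3,0,0,0,0,0,0,0,0,0,30
HCF4,0,0,0,0,0,0,0,0,0,31
HCF6,0,0,0,0,0,0,0,0,0,31
HCF7,0,0,0,0,0,0,0,0,0,32
HCF8,0,0,0,0,0,0,0,0,0,30
HCF9,0,0,0,0,0,0,0,0,0,27
HCM1,0,0,0,0,0,0,0,0,0,16
HCM2,0,0,0,0,0,0,0,0,0,25
HCM3,0,0,0,0,0,0,0,0,0,14
HCM4,0,0,0,0,0,0,0,0,0,24
HCM5,0,0,0,0,0,0,0,0,0,7
HCM6,0,0,0,0,0,0,0,0,0,22
L13,0,0,55,10,0,0,0,0,0,0
L14,0,11,27,6,0,0,11,0,0,0
M15,0,0,11,28,0,0,5,0,0,0
M16,0,0,8,0,0,0,23,0,13,0
M17,0,0,164,4,0,0,99,0,0,0
M18,0,0,1,0,0,0,2,0,10,20
M19,2,115,2,1,0,0,0,14,0,0
M20,0,0,21,1,0,2,7,0,0,2
M21,0,0,0,0,0,0,22,0,0,22
M22,0,0,10,18,0,0,38,0,0,22
O23,0,0,147,5,0,0,1,0,0,1
P24,0,0,63,22,0,0,3,0,0,0
P25,0,0,59,3,0,0,3,0,0,0
P26,0,0,2,8,0,1,0,0,0,0
R27,0,0,32,12,0,0,0,0,0,0
S28,0,0,69,47,20,0,39,0,0,1
T29,0,44,32,21,0,0,8,0,0,5
T30,0,0,37,7,0,0,0,0,0,0
T31,0,0,4,0,0,0,0,0,0,0
T32,0,20,31,0,0,13,0,24,0,0
T33,0,0,80,6,0,0,68,0,0,0
V34,0,27,28,0,0,0,5,2,4,0
V35,0,0,34,2,0,0,4,0,0,5
V36,0,0,0,0,0,0,5,0,0,6
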