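patient_id,device_id,item_id,level
F01,Ellipta,1,no
F01,Ellipta,2,yes
F01,Ellipta,3,no
F01,Ellipta,4,yes
F01,Ellipta,5,no
F01,Ellipta,6,yes
F01,Ellipta,7,no
F01,Ellipta,8,yes
F01,Ellipta,9,no
F01,Ellipta,10,moderate
F01,Ellipta,11,severe
F01,Ellipta,12,yes
F01,Breezhaler,1,yes
F01,Breezhaler,2,no
F01,Breezhaler,3,yes
F01,Breezhaler,4,no
F01,Breezhaler,5,yes
F01,Breezhaler,6,no
F01,Breezhaler,7,yes
F01,Breezhaler,8,no
F01,Breezhaler,9,yes
F01,Breezhaler,10,severe
F01,Breezhaler,11,none
F01,Breezhaler,12,no
F02,Spiromax,1,no
F02,Spiromax,2,yes
F02,Spiromax,3,no
F02,Spiromax,4,yes
F02,Spiromax,5,no
F02,Spiromax,6,yes
F02,Spiromax,7,no
F02,Spiromax,8,yes
F02,Spiromax,9,no
F02,Spiromax,10,none
F02,Spiromax,11,mild
F02,Spiromax,12,yes
F03,Ellipta,1,yes
F03,Ellipta,2,no
F03,Ellipta,3,yes
F03,Ellipta,4,no
F03,Ellipta,5,yes
F03,Ellipta,6,no
F03,Ellipta,7,yes
F03,Ellipta,8,no
F03,Ellipta,9,yes
F03,Ellipta,10,mild
F03,Ellipta,11,moderate
F03,Ellipta,12,no
F03,Breezhaler,1,no
F03,Breezhaler,2,yes
F03,Breezhaler,3,no
F03,Breezhaler,4,yes
F03,Breezhaler,5,no
F03,Breezhaler,6,yes
F03,Breezhaler,7,no
F03,Breezhaler,8,yes
F03,Breezhaler,9,no
F03,Breezhaler,10,moderate
F03,Breezhaler,11,severe
F03,Breezhaler,12,yes
F04,Spiromax,1,yes
F04,Spiromax,2,no
F04,Spiromax,3,yes
F04,Spiromax,4,no
F04,Spiromax,5,yes
F04,Spiromax,6,no
F04,Spiromax,7,yes
F04,Spiromax,8,no
F04,Spiromax,9,yes
F04,Spiromax,10,severe
F04,Spiromax,11,none
F04,Spiromax,12,no
F05,Ellipta,1,no
F05,Ellipta,2,yes
F05,Ellipta,3,no
F05,Ellipta,4,yes
F05,Ellipta,5,no
F05,Ellipta,6,yes
F05,Ellipta,7,no
F05,Ellipta,8,yes
F05,Ellipta,9,no
F05,Ellipta,10,none
F05,Ellipta,11,mild
F05,Ellipta,12,yes
F05,Breezhaler,1,yes
F05,Breezhaler,2,no
F05,Breezhaler,3,yes
F05,Breezhaler,4,no
F05,Breezhaler,5,yes
F05,Breezhaler,6,no
F05,Breezhaler,7,yes
F05,Breezhaler,8,no
F05,Breezhaler,9,yes
F05,Breezhaler,10,mild
F05,Breezhaler,11,moderate
F05,Breezhaler,12,no
F06,Spiromax,1,no
F06,Spiromax,2,yes
F06,Spiromax,3,no
F06,Spiromax,4,yes
F06,Spiromax,5,no
F06,Spiromax,6,yes
F06,Spiromax,7,no
F06,Spiromax,8,yes
F06,Spiromax,9,no
F06,Spiromax,10,moderate
F06,Spiromax,11,severe
F06,Spiromax,12,yes
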