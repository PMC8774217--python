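patient_id,device_id,sgus_total
F01,Breezhaler,25.8
F01,Ellipta,17.5
F02,Spiromax,32.7
F03,Breezhaler,17.5
F03,Ellipta,23.9
F04,Spiromax,25.8
F05,Breezhaler,23.9
F05,Ellipta,32.7
F06,Spiromax,17.5
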