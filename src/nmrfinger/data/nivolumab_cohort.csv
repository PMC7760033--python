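subject_id,arm,histology,cycles,ttf_weeks,ttf_ongoing,os_weeks,os_alive,pdl1_tps,ra_codes
MetL01,nivolumab,NA,4,8,0,10,0,,na (HP)
MetL05,nivolumab,NA,24,59,0,94,0,,iSD/PR;iSD;iUPD;iCPD
MetL06,nivolumab,NA,4,8,0,13,0,,iUPD
MetL07,nivolumab,NA,84,186,1,193,1,,iPR;iPR;iPR;iPR;iPR;iPR;iPR;iPR;iPR;iPR;iPR;iPR
MetL09,nivolumab,NA,19,38,0,67,0,,iSD;iUPD;iUPD;iCPD
MetL10,nivolumab,NA,10,18,0,20,0,,iSD;iSD
MetL11,nivolumab,NA,9,23,0,60,0,,iUPD;iCPD
MetL12,nivolumab,NA,23,45,0,60,0,,iUPD;iPR;iSD;iPD
MetL13,nivolumab,NA,29,140,1,167,1,,iUPD;iUPD;iPR;iPR;iUPD;iUPD;iPR;iSD;iSD;iSD
MetL15,nivolumab,NA,2,2,0,5,0,,na (HP)
MetL17,nivolumab,NA,19,41,0,103,0,,iUPD;iUPD;iCPD
MetL19,nivolumab,NA,27,66,0,104,0,,iUPD;iUPD;iSD;iSD;iCPD
MetL20,nivolumab,NA,4,6,0,8,0,,na (HP)
MetL24,nivolumab,NA,6,10,0,48,0,,iPD
MetL26,nivolumab,NA,6,10,0,36,0,,iPD
MetL29,nivolumab,NA,3,5,0,60,0,,na (HP)
MetL30,nivolumab,NA,2,4,0,14,0,,HP
MetL32,nivolumab,NA,8,17,0,19,0,,iUPD
MetL33,nivolumab,NA,13,35,0,41,0,,iSD;iSD;iUPD;iCPD
MetL34,nivolumab,NA,2,2,0,4,0,,na (HP)
MetL36,nivolumab,NA,8,16,0,21,0,,iUPD;iCPD
MetL37,nivolumab,NA,17,38,0,44,0,,iUPD;iUPD;iCPD
MetL39,nivolumab,NA,4,7,0,14,0,,iUPD
MetL40,nivolumab,NA,47,99,1,102,1,,iPR;iPR;iPR;iPR;iPR;iPR;iPR
MetL41,nivolumab,NA,6,12,0,23,0,,iUPD;iCPD
MetL42,nivolumab,NA,18,39,0,100,1,,iUPD;iUPD;iUPD;iCPD
MetL44,nivolumab,NA,11,20,0,92,1,,iUPD;iCPD
MetL45,nivolumab,NA,8,15,0,19,0,,iUPD;iCPD
MetL48,nivolumab,NA,19,37,0,75,1,,iUPD;iPR;iPD
MetL49,nivolumab,NA,1,1,0,1,0,,na (HP)
MetL50,nivolumab,NA,35,70,1,73,1,,iPR;iPR;iPR;iPR
MetL52,nivolumab,NA,29,58,1,70,1,,iUPD;iUPD;iUPD;iUPD;iUPD;iCPD
MetL53,nivolumab,NA,19,54,1,59,1,,iPR;iPR;iSD;iPR
MetL57,nivolumab,NA,7,15,0,52,1,,iUPD;iCPD
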