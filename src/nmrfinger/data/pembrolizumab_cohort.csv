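subject_id,arm,histology,cycles,ttf_weeks,ttf_ongoing,os_weeks,os_alive,pdl1_tps,ra_codes
MetL22,pembrolizumab,NA,35,115,1,118,1,80,iPR;iPR;iPR;iPR;iPR;iSD;iSD;iUPD;iSD
MetL23,pembrolizumab,NA,36,115,1,116,1,60,iPR;iPR;iCR;iCR;iCR;iSD;iSD;iSD
MetL25,pembrolizumab,NA,33,106,1,109,1,70,iSD;iSD;iSD;iSD;iSD;iSD;iSD;iSD;iSD
MetL27,pembrolizumab,NA,3,6,0,14,0,80,
MetL28,pembrolizumab,NA,8,24,0,39,0,70,iPR;iUPD;iCPD
MetL31,pembrolizumab,NA,3,8,0,10,0,70,
MetL35,pembrolizumab,NA,11,37,0,39,0,70,iSD;iUPD;iUPD;iCPD
MetL38,pembrolizumab,NA,26,82,1,87,1,60,iPR;iPR;iSD;iSD;iSD
MetL43,pembrolizumab,NA,1,5,0,5,0,60,
MetL46,pembrolizumab,NA,17,62,1,66,1,60,iUPD;iPR;iPR;iPR;iPR
MetL47,pembrolizumab,NA,17,54,1,56,1,80,iPR;iUPD;iSD
MetL51,pembrolizumab,NA,14,45,1,49,1,70,iPR;iPR;iSD
MetL55,pembrolizumab,NA,1,1,0,1,0,80,
MetL56,pembrolizumab,NA,3,9,0,17,0,90,iPD
MetL59,pembrolizumab,NA,3,6,0,,0,80,iPD
MetL60,pembrolizumab,NA,5,15,0,19,0,60,iSD
MetL63,pembrolizumab,NA,4,20,0,23,0,50,iUPD;iCPD
MetL65,pembrolizumab,NA,8,22,0,30,1,90,iPR;iUPD
MetL66,pembrolizumab,NA,7,,0,26,0,90,iUPD;iCPD
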