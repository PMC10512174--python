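patient_id,dheas_ug_dl,dheas_collection,albumin_g_dl,albumin_collection
C-M-1,NA,NA,3.5,32 days before death
C-M-2,NA,NA,3.4,within 24 h before death
C-M-3,287,within 24 h before death,3.6,within 24 h before death
C-M-4,16,within 24 h before death,3.8,within 24 h before death
C-M-5,76,within 24 h before death,3.8,within 24 h before death
C-M-6,16,within 24 h before death,3.4,within 24 h before death
C-M-7,66,within 24 h before death,4.7,within 24 h before death
C-F-1,82,within 24 h before death,3.5,within 24 h before death
C-F-2,66,within 24 h before death,2.8,within 24 h before death
C-F-3,127,within 24 h before death,3.6,within 24 h before death
C-F-4,NA,NA,3.2,within 24 h before death
C-F-5,45,within 24 h before death,2.7,within 24 h before death
C-F-6,39,within 24 h before death,4.3,within 24 h before death
C-F-7,NA,NA,NA,NA
P-M-1,210,3 days before death,2.4,3 days before death
P-M-2,146,2 days before death,0.9,within 24 h before death
P-M-3,14,3 days before death,1.5,1 day before death
P-M-4,29,1 day before death,1.5,1 day before death
P-M-5,17,1 day before death,1.6,within 24 h before death
P-M-6,NA,NA,2.0,4 days before death
P-M-7,59,4 days before death,1.4,1 day before death
P-M-8,68,3 days before death,2.0,1 day before death
P-M-9,NA,NA,1.4,10 days before death
P-M-10,28,1 day before death,1.3,within 24 h before death
P-F-1,53,6 days before death,0.9,within 24 h before death
P-F-2,44,1 day before death,1.2,1 day before death
P-F-3,67,5 days before death,1.9,3 days before death
P-F-4,125,2 days before death,2.0,within 24 h before death
P-F-5,NA,NA,2.3,4 days before death
P-F-6,210,2 days before death,2.8,1 day before death
P-F-7,NA,NA,2.8,28 days before death
P-F-8,NA,NA,2.7,23 days before death
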