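patient_id,rtl_zg,rtl_zf,rtl_zr,rtl_chromaffin
C-M-1,0.90,0.77,1.27,0.74
C-M-2,0.89,0.81,1.28,1.23
C-M-3,0.86,0.69,1.01,0.70
C-M-4,0.74,0.48,0.96,0.51
C-M-5,0.82,0.66,1.17,0.52
C-M-6,0.81,0.69,0.92,0.55
C-M-7,0.82,0.65,1.11,0.77
C-F-1,0.97,0.86,1.32,0.60
C-F-2,1.32,0.84,1.77,1.69
C-F-3,1.00,0.84,1.27,0.83
C-F-4,0.91,0.76,1.31,1.24
C-F-5,1.21,0.94,1.61,1.31
C-F-6,0.80,0.60,0.95,0.44
C-F-7,0.74,0.65,0.95,0.66
P-M-1,0.85,0.63,0.56,0.83
P-M-2,0.93,0.80,0.64,0.57
P-M-3,0.82,0.68,0.57,0.40
P-M-4,0.70,0.60,0.49,0.30
P-M-5,0.96,0.83,0.65,1.16
P-M-6,1.00,0.83,0.66,0.45
P-M-7,1.17,0.93,0.84,0.77
P-M-8,0.90,0.68,0.54,0.69
P-M-9,0.85,0.71,0.63,0.58
P-M-10,0.81,0.55,0.48,0.45
P-F-1,1.36,1.23,0.96,1.29
P-F-2,1.12,0.81,0.64,1.12
P-F-3,1.07,0.96,0.65,1.17
P-F-4,0.78,0.63,0.54,0.64
P-F-5,0.77,0.63,0.55,0.37
P-F-6,1.42,0.94,0.85,0.67
P-F-7,0.83,0.61,0.48,0.69
P-F-8,1.00,0.79,0.72,1.26
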