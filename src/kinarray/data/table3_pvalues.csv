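peptide_id,p_p3post,p_mm200,p_meljd
EGFR_1062_1074,3.71E-01,3.64E-01,1.84E-01
EGFR_1103_1115,2.10E-01,1.32E-01,2.32E-02
EGFR_1118_1130,1.14E-01,9.80E-01,6.97E-02
EGFR_1165_1177,6.90E-01,2.06E-02,4.82E-02
EGFR_1190_1202,5.20E-02,8.97E-01,1.69E-02
EGFR_862_874,3.99E-01,1.01E-03,4.49E-01
EGFR_908_920,8.03E-02,6.06E-01,2.96E-01
PGFRB_1002_1014,1.33E-01,2.45E-02,1.21E-02
PGFRB_1014_1028,1.72E-01,2.15E-02,1.40E-03
PGFRB_572_584,1.83E-01,8.84E-01,9.70E-02
PGFRB_709_721,3.28E-02,1.51E-02,1.77E-02
PGFRB_768_780,1.54E-01,2.96E-02,2.18E-05
PGFRB_771_783,2.12E-01,2.84E-02,5.52E-03
RAF1_332_344,8.41E-02,2.46E-02,5.11E-02
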