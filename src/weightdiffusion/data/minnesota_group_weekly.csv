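week,body_weight_kg,tee_kcal_day,intake_kcal_day,net_intake_kcal_day
0,69.39,1934.33,3538.72,1604.39
S1,68.35,1884.53,1658,-226.53
S2,66.8,1835.21,1658,-177.21
S3,65.76,1786.36,1648.88,-137.48
S4,64.29,1737.6,1610.88,-126.72
S5,63.33,1691.55,1645.94,-45.61
S6,62.16,1643.45,1639.16,-4.29
S7,61.11,1595.75,1639.03,43.28
S8,60.31,1548.28,1634.84,86.56
S9,59.56,1500.8,1620.41,119.61
S10,58.71,1453.31,1595.31,142
S11,58.14,1405.63,1578.72,173.09
S12,57.28,1357.94,1525.16,167.22
S13,56.6,1346.8,1515.69,168.89
S14,56.16,1335.67,1492.84,157.17
S15,55.69,1324.54,1459.94,135.4
S16,54.7,1313.39,1430.5,117.11
S17,54.28,1302.28,1488.81,186.53
S18,54.08,1291.1,1486.44,195.34
S19,53.51,1281.22,1519.72,238.5
S20,53.18,1271.34,1515.47,244.13
S21,52.99,1261.46,1538.75,277.29
S22,52.9,1251.58,1554.06,302.48
S23,52.83,1241.7,1581.19,339.49
S24,52.57,1231.83,1641.63,409.8
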