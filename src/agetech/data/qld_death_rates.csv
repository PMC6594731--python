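year,age_band,deaths_per_1000
2006,55-59,4.40
2006,60-64,7.00
2006,65-69,11.80
2006,70-74,19.00
2006,75-79,33.10
2006,80-84,59.70
2006,85-89,104.00
2006,90-94,186.90
2011,55-59,4.20
2011,60-64,6.60
2011,65-69,10.30
2011,70-74,17.70
2011,75-79,29.50
2011,80-84,54.90
2011,85-89,103.90
2011,90-94,183.40
2016,55-59,4.10
2016,60-64,6.00
2016,65-69,9.60
2016,70-74,15.50
2016,75-79,27.10
2016,80-84,49.80
2016,85-89,94.50
2016,90-94,167.50
2021,55-59,4.02
2021,60-64,5.42
2021,65-69,8.54
2021,70-74,12.30
2021,75-79,24.54
2021,80-84,42.96
2021,85-89,84.46
2021,90-94,154.74
2026,55-59,3.69
2026,60-64,4.84
2026,65-69,6.38
2026,70-74,12.17
2026,75-79,20.20
2026,80-84,40.55
2026,85-89,85.83
2026,90-94,154.88
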