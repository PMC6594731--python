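year,category,scenario,total_aud
2016,0,low,3458063
2016,1,low,11508369
2016,2,low,15052611
2016,3plus,low,16244548
2016,0,average,7864246
2016,1,average,20045598
2016,2,average,27092848
2016,3plus,average,28795217
2021,0,low,4124789
2021,1,low,13730378
2021,2,low,17954805
2021,3plus,low,19376552
2021,0,average,9380500
2021,1,average,23915956
2021,2,average,32316440
2021,3plus,average,34347032
2026,0,low,4999183
2026,1,low,16639688
2026,2,low,21760956
2026,3plus,low,23484092
2026,0,average,11369026
2026,1,average,28983473
2026,2,average,39167043
2026,3plus,average,41628090
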