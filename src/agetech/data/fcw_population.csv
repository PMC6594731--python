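year,age_band,persons
2006,55-59,12154
2006,60-64,9481
2006,65-69,7371
2006,70-74,5645
2006,75-79,4527
2006,80-84,2948
2006,85+,2349
2011,55-59,14281
2011,60-64,11703
2011,65-69,8720
2011,70-74,6387
2011,75-79,4762
2011,80-84,3432
2011,85+,2698
2016,55-59,15432
2016,60-64,12475
2016,65-69,10410
2016,70-74,7536
2016,75-79,5495
2016,80-84,3615
2016,85+,3258
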