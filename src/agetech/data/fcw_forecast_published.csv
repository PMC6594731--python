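year,age_band,persons
2021,60-64,15014
2021,65-69,11967
2021,70-74,9794
2021,75-79,6636
2021,80-84,4339
2021,85+,3423
2026,65-69,14558
2026,70-74,11262
2026,75-79,8828
2026,80-84,5313
2026,85+,3863
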