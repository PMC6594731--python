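region,year,persons
fcw,2006,210637
fcw,2011,229056
fcw,2016,236599
fcw,2021,235440
fcw,2026,220131
qld,2006,4007992
qld,2011,4476778
qld,2016,4848877
qld,2021,5191483
qld,2026,5835658
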