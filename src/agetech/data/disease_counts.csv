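n_diseases,persons_thousands
0,447.2
1,872.6
2,1004.3
3plus,962.4
total,3285.6
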