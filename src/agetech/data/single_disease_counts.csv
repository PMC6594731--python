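disease,persons_thousands
arthritis,237.8
asthma,28.4
back,95.6
cancer,15.9
copd,8.9
diabetes,57.3
cvd,389.1
mental,43.0
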