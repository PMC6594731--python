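disease_a,disease_b,persons_thousands
arthritis,asthma,202.5
arthritis,back,553.6
arthritis,cancer,89.8
arthritis,copd,174.5
arthritis,diabetes,299.1
arthritis,cvd,1059.1
arthritis,mental,368.0
asthma,back,126.8
asthma,cancer,23.8
asthma,copd,91.9
asthma,diabetes,80.3
asthma,cvd,215.2
asthma,mental,82.1
back,cancer,55.3
back,copd,106.0
back,diabetes,184.3
back,cvd,533.3
back,mental,209.9
cancer,copd,18.2
cancer,diabetes,39.5
cancer,cvd,128.6
cancer,mental,54.2
copd,diabetes,62.3
copd,cvd,188.7
copd,mental,84.8
diabetes,cvd,421.6
diabetes,mental,131.7
cvd,mental,378.1
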