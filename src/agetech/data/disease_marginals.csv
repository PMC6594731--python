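disease,persons_thousands
arthritis,1665.1
asthma,339.7
back,853.7
cancer,191.9
copd,257.5
diabetes,573.0
cvd,1920.5
mental,584.4
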