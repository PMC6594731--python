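age_band,p_need_assist,p_household,p_household_and_need
65-69,0.222,0.992,0.2203
70-74,0.291,0.986,0.2872
75-79,0.394,0.968,0.3820
80-84,0.568,0.923,0.5243
85-89,0.725,0.830,0.6018
90+,0.885,0.630,0.5578
total,0.386,0.948,0.3661
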