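# Abridged period life table: approximate US 2018 all-cause annual death
# probabilities (qx), blended ~70/30 female/male to reflect the predominantly
# female population treated for unruptured intracranial aneurysms.
# annual_mortality_probability applies to every age in [age_low, age_high).
age_low,age_high,annual_mortality_probability
0,45,0.0013
45,50,0.0030
50,55,0.0045
55,60,0.0068
60,65,0.0099
65,70,0.0142
70,75,0.0220
75,80,0.0354
80,85,0.0589
85,90,0.0996
90,95,0.1670
95,100,0.2658
100,125,0.3825
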