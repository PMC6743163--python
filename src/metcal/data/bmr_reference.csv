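sex,age_min,age_max,kcal_per_m2_per_h
female,18,29,34.3
female,30,39,33.2
female,40,49,32.7
female,50,59,31.6
female,60,69,30.7
female,70,79,29.9
male,18,29,37.5
male,30,39,36.3
male,40,49,35.4
male,50,59,34.2
male,60,69,33.1
male,70,79,32.2
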