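factor,male_paf_pct,female_paf_pct
tobacco_smoking,8.4,0.4
alcohol_drinking,8.7,1.1
overweight_obesity,4.9,5.8
physical_inactivity,8.9,9.0
low_vegetable_intake,18.8,16.8
low_fruit_intake,6.2,6.7
high_red_processed_meat,9.1,7.9
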