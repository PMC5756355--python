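factor,sex,region,level,prevalence,rr,rr_lo,rr_hi,is_reference,lower_bound
tobacco_smoking,male,national,ever_smoker,0.574,1.16,1.09,1.24,False,
tobacco_smoking,male,national,never_smoker,0.426,1.0,1.0,1.0,True,
tobacco_smoking,female,national,ever_smoker,0.026,1.16,1.09,1.24,False,
tobacco_smoking,female,national,never_smoker,0.974,1.0,1.0,1.0,True,
alcohol_drinking,male,national,drinker,0.396,1.24,1.01,1.54,False,
alcohol_drinking,male,national,non_drinker,0.604,1.0,1.0,1.0,True,
alcohol_drinking,female,national,drinker,0.045,1.24,1.01,1.54,False,
alcohol_drinking,female,national,non_drinker,0.955,1.0,1.0,1.0,True,
overweight_obesity,male,national,overweight,0.1503,1.25,1.07,1.45,False,
overweight_obesity,male,national,obese,0.0249,1.57,1.23,2.0,False,
overweight_obesity,male,national,normal_bmi,0.8248,1.0,1.0,1.0,True,
overweight_obesity,female,national,overweight,0.1697,1.25,1.07,1.45,False,
overweight_obesity,female,national,obese,0.0341,1.57,1.23,2.0,False,
overweight_obesity,female,national,normal_bmi,0.7962,1.0,1.0,1.0,True,
physical_inactivity,male,national,inactive,0.304,1.32,1.23,1.41,False,
physical_inactivity,male,national,active,0.696,1.0,1.0,1.0,True,
physical_inactivity,female,national,inactive,0.368,1.27,1.17,1.41,False,
physical_inactivity,female,national,active,0.632,1.0,1.0,1.0,True,
low_vegetable_intake,male,urban,quintile_1,0.2,1.52,1.14,1.95,False,0
low_vegetable_intake,male,urban,quintile_2,0.2,1.3,1.09,1.51,False,166.7
low_vegetable_intake,male,urban,quintile_3,0.2,1.2,1.06,1.34,False,250.0
low_vegetable_intake,male,urban,quintile_4,0.2,1.12,1.04,1.19,False,325.0
low_vegetable_intake,male,urban,quintile_5,0.2,1.0,1.0,1.0,True,441.7
low_vegetable_intake,female,urban,quintile_1,0.2,1.46,1.13,1.83,False,0
low_vegetable_intake,female,urban,quintile_2,0.2,1.27,1.08,1.46,False,150.0
low_vegetable_intake,female,urban,quintile_3,0.2,1.18,1.05,1.3,False,225.0
low_vegetable_intake,female,urban,quintile_4,0.2,1.1,1.03,1.16,False,300.0
low_vegetable_intake,female,urban,quintile_5,0.2,1.0,1.0,1.0,True,400.0
low_vegetable_intake,male,rural,quintile_1,0.2,1.5,1.14,1.92,False,0
low_vegetable_intake,male,rural,quintile_2,0.2,1.3,1.09,1.52,False,155.0
low_vegetable_intake,male,rural,quintile_3,0.2,1.21,1.06,1.35,False,233.3
low_vegetable_intake,male,rural,quintile_4,0.2,1.12,1.04,1.19,False,316.7
low_vegetable_intake,male,rural,quintile_5,0.2,1.0,1.0,1.0,True,433.3
low_vegetable_intake,female,rural,quintile_1,0.2,1.46,1.13,1.83,False,0
low_vegetable_intake,female,rural,quintile_2,0.2,1.27,1.08,1.46,False,150.0
low_vegetable_intake,female,rural,quintile_3,0.2,1.19,1.06,1.31,False,220.0
low_vegetable_intake,female,rural,quintile_4,0.2,1.1,1.03,1.16,False,300.0
low_vegetable_intake,female,rural,quintile_5,0.2,1.0,1.0,1.0,True,400.0
low_fruit_intake,male,urban,quintile_1,0.2,1.12,1.04,1.21,False,0
low_fruit_intake,male,urban,quintile_2,0.2,1.09,1.03,1.15,False,50.0
low_fruit_intake,male,urban,quintile_3,0.2,1.06,1.02,1.11,False,83.3
low_fruit_intake,male,urban,quintile_4,0.2,1.04,1.01,1.07,False,116.7
low_fruit_intake,male,urban,quintile_5,0.2,1.0,1.0,1.0,True,183.3
low_fruit_intake,female,urban,quintile_1,0.2,1.13,1.04,1.23,False,0
low_fruit_intake,female,urban,quintile_2,0.2,1.1,1.03,1.17,False,50.0
low_fruit_intake,female,urban,quintile_3,0.2,1.07,1.02,1.13,False,83.3
low_fruit_intake,female,urban,quintile_4,0.2,1.05,1.02,1.09,False,116.7
low_fruit_intake,female,urban,quintile_5,0.2,1.0,1.0,1.0,True,200.0
low_fruit_intake,male,rural,quintile_1,0.2,1.12,1.04,1.2,False,0
low_fruit_intake,male,rural,quintile_2,0.2,1.09,1.03,1.16,False,33.3
low_fruit_intake,male,rural,quintile_3,0.2,1.07,1.02,1.12,False,66.7
low_fruit_intake,male,rural,quintile_4,0.2,1.06,1.02,1.1,False,88.3
low_fruit_intake,male,rural,quintile_5,0.2,1.0,1.0,1.0,True,176.7
low_fruit_intake,female,rural,quintile_1,0.2,1.16,1.05,1.28,False,0
low_fruit_intake,female,rural,quintile_2,0.2,1.13,1.04,1.23,False,33.3
low_fruit_intake,female,rural,quintile_3,0.2,1.11,1.03,1.19,False,66.7
low_fruit_intake,female,rural,quintile_4,0.2,1.09,1.03,1.15,False,100.0
low_fruit_intake,female,rural,quintile_5,0.2,1.0,1.0,1.0,True,233.3
high_red_processed_meat,male,urban,quintile_1,0.2,1.0,1.0,1.0,True,0
high_red_processed_meat,male,urban,quintile_2,0.2,1.07,1.02,1.11,False,50.0
high_red_processed_meat,male,urban,quintile_3,0.2,1.12,1.03,1.2,False,83.3
high_red_processed_meat,male,urban,quintile_4,0.2,1.17,1.05,1.29,False,120.0
high_red_processed_meat,male,urban,quintile_5,0.2,1.27,1.07,1.48,False,183.3
high_red_processed_meat,female,urban,quintile_1,0.2,1.0,1.0,1.0,True,0
high_red_processed_meat,female,urban,quintile_2,0.2,1.04,1.01,1.07,False,33.3
high_red_processed_meat,female,urban,quintile_3,0.2,1.09,1.03,1.15,False,66.7
high_red_processed_meat,female,urban,quintile_4,0.2,1.14,1.04,1.24,False,100.0
high_red_processed_meat,female,urban,quintile_5,0.2,1.22,1.06,1.38,False,150.0
high_red_processed_meat,male,rural,quintile_1,0.2,1.0,1.0,1.0,True,0
high_red_processed_meat,male,rural,quintile_2,0.2,1.04,1.01,1.07,False,33.3
high_red_processed_meat,male,rural,quintile_3,0.2,1.08,1.02,1.14,False,60.0
high_red_processed_meat,male,rural,quintile_4,0.2,1.12,1.03,1.21,False,86.7
high_red_processed_meat,male,rural,quintile_5,0.2,1.2,1.06,1.34,False,136.7
high_red_processed_meat,female,rural,quintile_1,0.2,1.0,1.0,1.0,True,0
high_red_processed_meat,female,rural,quintile_2,0.2,1.04,1.01,1.07,False,33.3
high_red_processed_meat,female,rural,quintile_3,0.2,1.07,1.02,1.11,False,50.0
high_red_processed_meat,female,rural,quintile_4,0.2,1.12,1.03,1.2,False,83.3
high_red_processed_meat,female,rural,quintile_5,0.2,1.17,1.05,1.29,False,116.7
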