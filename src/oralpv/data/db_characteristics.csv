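database,variable,category,count,pct_printed
pei,total,total,974931,
pei,sex,female,694572,71.98
pei,sex,male,270362,28.02
pei,sex,missing,9997,1.03
pei,age_group,under2,66,0.01
pei,age_group,2to6,801,0.09
pei,age_group,7to17,16129,1.72
pei,age_group,18to59,773889,82.59
pei,age_group,over59,146154,15.6
pei,age_group,missing,37892,3.89
pei,vaccine_type,mrna,745174,76.88
pei,vaccine_type,viral_vector,220371,22.74
pei,vaccine_type,protein_subunit,3658,0.38
pei,vaccine_type,inactivated,18,<0.01
pei,vaccine_type,missing,5710,0.59
pei,schedule,primer,962881,99.35
pei,schedule,booster,6340,0.65
pei,schedule,missing,5710,0.59
pei,year,2020,113,0.01
pei,year,2021,601610,61.71
pei,year,2022,317453,32.56
pei,year,2023,55755,5.72
vaers,total,total,1016024,
vaers,sex,female,647009,66.50
vaers,sex,male,325929,33.50
vaers,sex,missing,43086,4.24
vaers,age_group,under2,2807,0.31
vaers,age_group,2to6,8917,0.98
vaers,age_group,7to17,51139,5.61
vaers,age_group,18to59,516801,56.65
vaers,age_group,over59,332564,36.46
vaers,age_group,missing,103796,10.22
vaers,vaccine_type,mrna,939716,92.73
vaers,vaccine_type,viral_vector,73201,7.22
vaers,vaccine_type,protein_subunit,511,0.05
vaers,vaccine_type,missing,2596,0.26
vaers,schedule,primer,972752,95.99
vaers,schedule,booster,40676,4.01
vaers,schedule,missing,2596,0.26
vaers,year,2020,10380,1.02
vaers,year,2021,710616,69.94
vaers,year,2022,210534,20.72
vaers,year,2023,71074,7.00
vaers,year,2024,13420,1.32
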