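sex,year,quintile,deaths,population,published_rate_per_1000
male,2011,Q1,35217,5256845,6.69
male,2011,Q2,39405,5073220,7.77
male,2011,Q3,41134,4759007,8.64
male,2011,Q4,39745,4270710,9.31
male,2011,Q5,39523,3921491,10.08
male,2012,Q1,36126,5288462,6.83
male,2012,Q2,40656,5075266,8.01
male,2012,Q3,42394,4750182,8.92
male,2012,Q4,41073,4254020,9.65
male,2012,Q5,40949,3888492,10.53
male,2013,Q1,35551,5272262,6.74
male,2013,Q2,39766,5039926,7.89
male,2013,Q3,40643,4703703,8.64
male,2013,Q4,39752,4194731,9.48
male,2013,Q5,39314,3832194,10.26
female,2011,Q1,38283,5657980,6.77
female,2011,Q2,37608,5270843,7.14
female,2011,Q3,37515,4853180,7.13
female,2011,Q4,35979,4277989,8.41
female,2011,Q5,34734,3845162,9.03
female,2012,Q1,39696,5699851,6.96
female,2012,Q2,39340,5286365,7.44
female,2012,Q3,39459,4854909,8.13
female,2012,Q4,37451,4268555,8.77
female,2012,Q5,37020,3815310,9.70
female,2013,Q1,38846,5691572,6.83
female,2013,Q2,38137,5266307,7.24
female,2013,Q3,38004,4824427,7.88
female,2013,Q4,36221,4224892,8.57
female,2013,Q5,35242,3772367,9.34
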