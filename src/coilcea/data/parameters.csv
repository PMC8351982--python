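id,name,mean,se,dist_family,source_duration_years,sens_low,sens_high,group,order_group,order_rank
1,Probability of mild disability (mRS 1-2) from a coiling procedure,0.048,0.005944,beta,0,0.0361,0.0599,probability,,
2,Probability of moderate-severe disability (mRS 3-5) from a coiling procedure,0.022,0.002730,beta,0,0.0165,0.0275,probability,,
3,Probability of death from a coiling procedure,0.02,0.002136,beta,0,0.0157,0.0243,probability,,
4,Probability of developing a recanalization,0.244,0.03592,beta,6,0.1722,0.3158,probability,,
5,Probability of coiled aneurysm re-treatment,0.091,0.01340,beta,6,0.0642,0.1178,probability,,
6,Probability of developing a de novo aneurysm,0.006,0.001352,beta,1,0.00330,0.00870,probability,,
7,Probability of aSAH with an untreated aneurysm,0.014,0.001275,beta,1,0.0114,0.0166,probability,,
8,Probability of death from aSAH prior to reaching hospital,0.124,0.007653,beta,0,0.1087,0.1393,probability,,
9,Probability of death from aSAH after reaching hospital,0.265,0.002005,beta,0,0.2610,0.2690,probability,,
10,Probability of mild disability (mRS 1-2) from aSAH,0.2665,0.002010,beta,0,0.26248,0.27052,probability,,
11,Probability of moderate-severe disability (mRS 3-5) from aSAH,0.1475,0.001612,beta,0,0.14428,0.15072,probability,,
12,Coiling procedure without complications,30013,15905,truncated_ordered_normal,0,0,46473,cost,procedure_cost,1
13,Coiling procedure with complications leading to functional disability,47237,22306,truncated_ordered_normal,0,30889,83016,cost,procedure_cost,2
14,Coiling procedure with complications leading to death,65336,58090,truncated_ordered_normal,0,48688,181515,cost,procedure_cost,3
15,Annual care of coiled patient with good function (mRS 0),11197,2799,truncated_ordered_normal,0,5598,12072,cost,care_cost,1
16,Annual care of coiled patient with mild disability (mRS 1-2),12132,3033,truncated_ordered_normal,0,11259,18198,cost,care_cost,2
17,Annual care of coiled patient with moderate-severe disability (mRS 3-5),42257,10564,truncated_ordered_normal,0,21128,63385,cost,care_cost,3
18,Hospital care for aSAH,93440,539,gamma,0,92362,94517,cost,,
19,Utility coiled with good functional status (mRS 0) age 45-54,0.87,0.01,truncated_ordered_normal,0,0.840,0.880,utility,utility,1
20,Utility coiled with mild disability (mRS 1-2),0.72,0.025,truncated_ordered_normal,0,0.670,0.770,utility,utility,2
21,Utility coiled with moderate-severe disability (mRS 3-5),0.41,0.085,truncated_ordered_normal,0,0.240,0.580,utility,utility,3
22,Disutility of having an untreated aneurysm,-0.07,0.04082,beta,0,0,-0.152,utility,,
23,Utility during aSAH cycle,0.41,0.085,truncated_ordered_normal,0,0.240,0.580,utility,,
24,HTI efficacy (relative risk reduction of recanalization),0.5,0,uniform,0,,,hti,,
25,Cost of HTI,10000,0,deterministic,0,,,hti,,
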