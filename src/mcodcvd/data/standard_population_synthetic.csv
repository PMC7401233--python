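age_lo,age_hi,weight
0,5,0.08857342797
5,10,0.086873937819
10,15,0.085974207738
15,20,0.084674597621
20,25,0.082175347396
25,30,0.079276217135
30,35,0.076077176847
35,40,0.071478556433
40,45,0.065880235929
45,50,0.060381885434
50,55,0.053683894832
55,60,0.045486354094
60,65,0.037188843347
65,70,0.029591122663
70,75,0.022093371988
75,80,0.015195441368
80,85,0.009097270819
85,90,0.004398680396
90,95,0.001499550135
95,,0.000399880036
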