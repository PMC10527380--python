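label,start_age,stop_age,packyear_criterion,cost_usd,qalys
No screening,,,,552.87,15.64662
1,65,74,30,600.45,15.64870
2,65,79,30,614.10,15.64928
3,65,74,20,639.36,15.65034
4,65,79,20,664.10,15.65136
5,60,79,20,718.69,15.65341
6,55,79,20,775.74,15.65504
7,50,79,20,834.48,15.65598
8,45,79,20,898.24,15.65627
9,40,79,20,986.37,15.65663
2018 guideline,50,74,20,809.74,15.65496
2021 guideline,50,74,30,693.13,15.65132
2022 guideline,45,74,20,873.51,15.65525
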