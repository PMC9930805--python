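age_years,score
3.0,25.35
3.5,28.77
4.0,32.05
4.5,35.19
5.0,38.20
5.5,41.07
6.0,43.81
6.5,46.41
7.0,48.87
7.5,51.20
8.0,53.39
8.5,55.45
9.0,57.37
9.5,59.15
10.0,60.80
10.5,62.31
11.0,63.69
11.5,64.93
12.0,66.03
12.5,67.00
13.0,67.83
13.5,68.53
14.0,69.09
14.5,69.51
15.0,69.80
15.5,69.95
16.0,69.97
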