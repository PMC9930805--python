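age_years,score
3.0,26.20
3.5,29.30
4.0,32.28
4.5,35.14
5.0,37.88
5.5,40.49
6.0,42.98
6.5,45.35
7.0,47.59
7.5,49.72
8.0,51.72
8.5,53.60
9.0,55.36
9.5,56.99
10.0,58.50
10.5,59.89
11.0,61.16
11.5,62.30
12.0,63.32
12.5,64.22
13.0,64.99
13.5,65.65
14.0,66.18
14.5,66.59
15.0,66.88
15.5,67.04
16.0,67.08
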