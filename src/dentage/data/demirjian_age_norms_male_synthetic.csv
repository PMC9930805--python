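age_years,score
3.0,3.2
3.5,4.2
4.0,5.4
4.5,7.0
5.0,9.0
5.5,11.6
6.0,14.7
6.5,18.5
7.0,23.0
7.5,28.2
8.0,34.1
8.5,40.5
9.0,47.3
9.5,54.1
10.0,60.8
10.5,67.2
11.0,72.9
11.5,78.0
12.0,82.3
12.5,86.0
13.0,89.0
13.5,91.4
14.0,93.3
14.5,94.9
15.0,96.0
15.5,97.0
16.0,97.7
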