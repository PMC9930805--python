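age_years,score
3.0,3.3
3.5,4.4
4.0,5.8
4.5,7.6
5.0,9.9
5.5,12.9
6.0,16.5
6.5,20.8
7.0,26.0
7.5,32.0
8.0,38.6
8.5,45.7
9.0,52.9
9.5,60.0
10.0,66.7
10.5,72.8
11.0,78.2
11.5,82.7
12.0,86.5
12.5,89.5
13.0,92.0
13.5,93.9
14.0,95.3
14.5,96.5
15.0,97.3
15.5,98.0
16.0,98.5
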