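tooth,stage,score
31,0,0.00
31,A,0.47
31,B,1.06
31,C,1.89
31,D,3.30
31,E,5.55
31,F,7.79
31,G,10.03
31,H,11.80
32,0,0.00
32,A,0.49
32,B,1.10
32,C,1.95
32,D,3.42
32,E,5.73
32,F,8.05
32,G,10.37
32,H,12.20
33,0,0.00
33,A,0.54
33,B,1.21
33,C,2.14
33,D,3.75
33,E,6.30
33,F,8.84
33,G,11.39
33,H,13.40
34,0,0.00
34,A,0.55
34,B,1.24
34,C,2.21
34,D,3.86
34,E,6.49
34,F,9.11
34,G,11.73
34,H,13.80
35,0,0.00
35,A,0.57
35,B,1.29
35,C,2.29
35,D,4.00
35,E,6.72
35,F,9.44
35,G,12.16
35,H,14.30
36,0,0.00
36,A,0.62
36,B,1.40
36,C,2.48
36,D,4.34
36,E,7.28
36,F,10.23
36,G,13.17
36,H,15.50
37,0,0.00
37,A,0.76
37,B,1.71
37,C,3.04
37,D,5.32
37,E,8.93
37,F,12.54
37,G,16.15
37,H,19.00
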