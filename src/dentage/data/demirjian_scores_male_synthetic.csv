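tooth,stage,score
31,0,0.00
31,A,0.46
31,B,1.03
31,C,1.84
31,D,3.22
31,E,5.40
31,F,7.59
31,G,9.78
31,H,11.50
32,0,0.00
32,A,0.48
32,B,1.08
32,C,1.92
32,D,3.36
32,E,5.64
32,F,7.92
32,G,10.20
32,H,12.00
33,0,0.00
33,A,0.52
33,B,1.17
33,C,2.08
33,D,3.64
33,E,6.11
33,F,8.58
33,G,11.05
33,H,13.00
34,0,0.00
34,A,0.56
34,B,1.26
34,C,2.24
34,D,3.92
34,E,6.58
34,F,9.24
34,G,11.90
34,H,14.00
35,0,0.00
35,A,0.58
35,B,1.30
35,C,2.32
35,D,4.06
35,E,6.81
35,F,9.57
35,G,12.32
35,H,14.50
36,0,0.00
36,A,0.64
36,B,1.44
36,C,2.56
36,D,4.48
36,E,7.52
36,F,10.56
36,G,13.60
36,H,16.00
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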