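cluster_a,cluster_b,height,size
8.000000000,9.000000000,0.000723185,2.000000000
0.000000000,11.000000000,0.001413081,2.000000000
6.000000000,7.000000000,0.001833622,2.000000000
2.000000000,13.000000000,0.002021614,3.000000000
3.000000000,4.000000000,0.002040150,2.000000000
1.000000000,10.000000000,0.003501389,2.000000000
14.000000000,16.000000000,0.004665698,4.000000000
12.000000000,15.000000000,0.004734201,5.000000000
17.000000000,18.000000000,0.007368619,6.000000000
5.000000000,19.000000000,0.008323893,6.000000000
20.000000000,21.000000000,0.424485049,12.000000000
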