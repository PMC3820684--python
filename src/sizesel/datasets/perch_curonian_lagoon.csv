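# Curonian Lagoon European perch: catch numbers by 1-cm length class
# for eight gillnet mesh sizes (mm) and Great Cormorants (GC)
# normalized: false
# predators: GC
length_class,G14,G17,G21.5,G25,G30,G33,G38,G45,GC
2,0,0,0,0,0,0,0,0,1
3,0,0,0,0,0,0,0,0,13
4,0,0,0,0,0,0,0,0,71
5,0,0,0,0,0,0,0,0,250
6,0,0,0,0,0,0,0,0,244
7,0,0,0,0,0,0,0,0,588
8,0,0,0,0,0,0,0,0,952
9,0,0,0,0,0,0,0,0,587
10,5,0,0,0,0,0,0,0,251
11,46,5,0,0,0,0,0,0,128
12,30,22,0,0,0,0,0,0,93
13,37,54,2,2,0,0,1,0,81
14,12,37,6,2,1,0,0,0,82
15,1,19,15,0,1,1,0,0,111
16,5,3,28,5,0,0,0,0,79
17,2,4,23,31,2,0,1,1,70
18,0,3,16,42,1,0,0,2,39
19,0,3,10,35,6,1,0,1,40
20,1,1,9,22,13,2,1,0,28
21,0,3,3,16,18,7,0,1,18
22,0,1,4,11,11,18,0,0,14
23,0,2,4,5,12,10,0,0,8
24,0,0,0,4,7,4,4,0,6
25,0,1,0,4,5,7,10,1,4
26,0,0,1,3,8,6,20,1,4
27,0,0,1,2,7,1,21,1,1
28,0,0,2,1,3,1,14,1,2
29,0,0,0,1,3,0,9,4,0
30,0,0,0,0,1,0,4,10,0
31,0,0,0,0,1,0,4,9,1
32,0,0,0,0,0,0,1,5,0
33,0,0,0,0,0,0,0,2,0
34,0,0,0,0,0,0,0,1,0
35,0,0,0,0,1,0,1,0,0
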