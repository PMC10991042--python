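time,phase,y
-11,A,48
-10,A,43
-9,A,35
-8,A,43
-7,A,42
-6,A,47
-5,A,44
-4,A,46
-3,A,47
-2,A,47
-1,A,50
0,B,48
1,B,47
2,B,41
3,B,30
4,B,35
5,B,38
6,B,32
7,B,28
8,B,26
9,B,35
10,B,38
11,B,40
12,B,30
13,B,34
14,B,37
15,B,38
16,B,42
17,B,40
18,B,46
19,B,42
20,B,34
21,B,27
23,B,29
24,B,28
25,B,21
26,B,24
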