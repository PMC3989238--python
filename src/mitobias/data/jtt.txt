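# JTT (Jones-Taylor-Thornton 1992) amino-acid replacement model.
# Line 1: residue order. Next 190 lines: lower-triangular exchangeabilities
# (row 2..20 against preceding residues). Final 20 lines: equilibrium frequencies.
A R N D C Q E G H I L K M F P S T W Y V
58
54
81
56
57
105
179
27
36
30
35
54
15
194
378
475
9
11
298
45
16
113
310
29
137
328
22
38
646
44
5
74
101
64
126
20
17
528
34
86
58
81
391
47
12
263
30
10
15
503
232
8
70
16
10
49
767
130
112
11
7
26
15
4
15
59
38
4
46
31
9
5
59
69
17
23
7
31
78
14
223
42
115
209
62
323
26
597
9
72
292
43
4
164
53
51
18
24
20
119
26
12
9
181
18
5
18
30
32
10
7
45
23
6
6
27
14
5
24
201
33
55
8
47
16
56
45
33
40
115
73
46
8
573
11
229
21
479
89
10
40
245
9
32
961
14
388
248
102
59
25
52
24
180
65
4
21
47
103
10
8
14
43
16
29
226
24
18
323
17
92
12
53
536
62
285
118
6
10
23
477
35
63
38
12
21
112
71
25
16
0.07674792325
0.05169094831
0.04264495736
0.05154394846
0.01980298020
0.04075195925
0.06182993817
0.07315192685
0.02294397706
0.05376094624
0.09190390810
0.05867594132
0.02382597617
0.04012595987
0.05090094910
0.06876493124
0.05856494144
0.01426098574
0.03210196790
0.06600493400
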