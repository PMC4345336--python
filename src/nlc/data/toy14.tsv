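1	2
1	3
1	4
1	5
2	3
2	4
2	5
3	4
3	5
4	5
5	6
5	7
5	8
5	9
6	7
6	8
6	9
7	8
7	9
8	9
10	11
10	12
10	13
10	14
11	12
11	13
11	14
12	13
12	14
13	14
9	10
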