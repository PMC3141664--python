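category	0	1	2	3	4	5	6	7	8
0	9213	2947	3	0	0	0	0	0	0
1	1990	24845	4269	150	0	0	0	0	0
2	0	818	4884	2273	24	0	0	0	0
3	0	16	402	3293	1028	2	0	0	0
4	1	2	2	172	1669	415	2	1	0
5	0	0	0	1	76	749	213	0	0
6	0	0	0	0	0	35	357	108	0
7	0	0	0	0	0	0	11	241	9
8	0	0	0	0	0	0	0	2	54
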