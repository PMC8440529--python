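chrom	length	is_autosome
1	249250621	1
2	243199373	1
3	198022430	1
4	191154276	1
5	180915260	1
6	171115067	1
7	159138663	1
8	146364022	1
9	141213431	1
10	135534747	1
11	135006516	1
12	133851895	1
13	115169878	1
14	107349540	1
15	102531392	1
16	90354753	1
17	81195210	1
18	78077248	1
19	59128983	1
20	63025520	1
21	48129895	1
22	51304566	1
X	155270560	0
Y	59373566	0
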