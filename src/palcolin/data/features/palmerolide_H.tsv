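# palcolin feature table v1
# bgc_id: palmerolide_H
# n_elongations: 12
# post_nrps_elongations: 11
# backbone_carbons: 26
# polyketide_carbons: 24
# total_carbons: 35
# starter: 3-methyl-3-butenoic acid
# amino_acids: glycine
# amide: true
# hydrolyzed: false
# tail_units: 1
# tail_methyls: 1
# ring: 1,19
position	state	stereo	olefin	geometry	branch	branch_mode	decoration
1	ester_carbonyl	.	.	.	.	.	.
2	olefinic	.	D2	trans	.	.	.
3	olefinic	.	.	.	.	.	.
4	methylene	.	.	.	.	.	.
5	methylene	.	.	.	.	.	.
6	methylene	.	.	.	.	.	.
7	hydroxyl	D	.	.	.	.	carbamate
8	hydroxyl	.	.	.	.	.	.
9	olefinic	.	D9	trans	.	.	.
10	olefinic	.	.	.	.	.	.
11	hydroxyl	D	.	.	.	.	sulfate
12	methylene	.	.	.	.	.	.
13	methylene	.	.	.	.	.	.
14	olefinic	.	D14	trans	.	.	.
15	olefinic	.	.	.	.	.	.
16	olefinic	.	D16	.	.	.	.
17	olefinic	.	.	.	C27	internal	.
18	methylene	.	.	.	.	.	.
19	hydroxyl	L	.	.	.	.	macrolactone
20	methylene	.	.	.	C28	.	.
21	olefinic	.	D21	trans	.	.	.
22	olefinic	.	.	.	C29	.	.
23	olefinic	.	D23	.	.	.	.
24	olefinic	.	.	.	.	.	.
25	carbonyl	.	.	.	.	.	.
26	methylene	.	.	.	C30	.	.
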