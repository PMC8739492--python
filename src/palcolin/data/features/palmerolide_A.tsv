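# palcolin feature table v1
# bgc_id: palmerolide_A
# n_elongations: 11
# post_nrps_elongations: 11
# backbone_carbons: 24
# polyketide_carbons: 22
# total_carbons: 32
# starter: 3-methylcrotonic acid
# amino_acids: glycine
# amide: true
# hydrolyzed: false
# tail_units: 0
# tail_methyls: 0
# ring: 1,19
position	state	stereo	olefin	geometry	branch	branch_mode	decoration
1	ester_carbonyl	.	.	.	.	.	.
2	olefinic	.	D2	trans	.	.	.
3	olefinic	.	.	.	.	.	.
4	methylene	.	.	.	.	.	.
5	methylene	.	.	.	.	.	.
6	methylene	.	.	.	.	.	.
7	hydroxyl	D	.	.	.	.	.
8	olefinic	.	D8	trans	.	.	.
9	olefinic	.	.	.	.	.	.
10	hydroxyl	.	.	.	.	.	.
11	hydroxyl	D	.	.	.	.	carbamate
12	methylene	.	.	.	.	.	.
13	methylene	.	.	.	.	.	.
14	olefinic	.	D14	trans	.	.	.
15	olefinic	.	.	.	.	.	.
16	olefinic	.	D16	.	.	.	.
17	olefinic	.	.	.	C25	internal	.
18	methylene	.	.	.	.	.	.
19	hydroxyl	L	.	.	.	.	macrolactone
20	methylene	.	.	.	C26	.	.
21	olefinic	.	D21	trans	.	.	.
22	olefinic	.	.	.	C27	.	.
23	olefinic	.	D23	.	.	.	.
24	olefinic	.	.	.	.	.	.
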