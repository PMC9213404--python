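chrom	pos	tsd_seq	VnP1	VnP2	VnP3	both_tsd	flanking_gene
SSC1	38667241	CTAT	LTR	LTR	LTR	1	NKAIN2
SSC1	256173876	CCCC	PERV-B	PERV-B	LTR	1	ENSSSCG00000046664
SSC1	259647577	AATC	LTR	LTR	LTR	1	.
SSC2	3400723	AGAAC	PERV-B	LTR	LTR	1	.
SSC4	77324504	CCCC	LTR	LTR	LTR	1	.
SSC4	78524842	ATTAC	LTR	LTR	LTR	1	SNTG1
SSC4	121221912	GGGG	LTR	LTR	non-LTR	1	.
SSC6	73460691	GTAT	LTR	LTR	LTR	1	KAZN
SSC8	137488280	CTAT	LTR	LTR	LTR	1	CFAP299
SSC9	61533579	GGTG	LTR	LTR	non-LTR	1	.
SSC9	76895449	GAAC	PERV-B	PERV-B	PERV-B	1	.
SSC9	135717008	AAGAG	LTR	LTR	LTR	1	.
SSC12	60076460	CTGCT	PERV-B	PERV-B	PERV-B	1	LOC110256117
SSC13	57502585	TAAA	LTR	LTR	LTR	1	.
SSC13	60210737	GTAG	LTR	LTR	non-LTR	1	LOC106505659
SSC13	73434304	TTAT	LTR	LTR	non-LTR	1	.
SSC14	4896607	AGGGT	LTR	LTR	non-LTR	1	.
SSC14	27599572	ATGC	PERV-B	PERV-B	LTR	1	.
SSCX	70665683	ATAT	PERV-B	PERV-B	PERV-B	1	LOC102165634
SSCX	75151968	CCAG	PERV-B	PERV-B	PERV-B	1	PCDH11X
SSCX	119479008	AATT	LTR	LTR	non-LTR	1	.
SSC8	51601922	ATGA	PERV-C	PERV-C	PERV-C	0	LOC106504658
SSC8	137628915	ATGAC	non-LTR	non-LTR	LTR	0	ANTXR2
SSC13	107045657	ATTC	PERV-A	non-LTR	non-LTR	0	LOC100153543
SSC14	8846347	GAGG	LTR	LTR	non-LTR	0	.
SSC18	4030456	ATGT	non-LTR	non-LTR	non-LTR	0	.
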