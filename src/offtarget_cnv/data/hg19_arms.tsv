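chrom	arm	start	end	comparable
chr1	p	0	125000000	1
chr1	q	125000000	249250621	1
chr2	p	0	93300000	1
chr2	q	93300000	243199373	1
chr3	p	0	91000000	1
chr3	q	91000000	198022430	1
chr4	p	0	50400000	1
chr4	q	50400000	191154276	1
chr5	p	0	48400000	1
chr5	q	48400000	180915260	1
chr6	p	0	61000000	1
chr6	q	61000000	171115067	1
chr7	p	0	59900000	1
chr7	q	59900000	159138663	1
chr8	p	0	45600000	1
chr8	q	45600000	146364022	1
chr9	p	0	49000000	1
chr9	q	49000000	141213431	1
chr10	p	0	40200000	1
chr10	q	40200000	135534747	1
chr11	p	0	53700000	1
chr11	q	53700000	135006516	1
chr12	p	0	35800000	1
chr12	q	35800000	133851895	1
chr13	p	0	17900000	0
chr13	q	17900000	115169878	1
chr14	p	0	17600000	0
chr14	q	17600000	107349540	1
chr15	p	0	19000000	0
chr15	q	19000000	102531392	1
chr16	p	0	36600000	1
chr16	q	36600000	90354753	1
chr17	p	0	24000000	1
chr17	q	24000000	81195210	1
chr18	p	0	17200000	1
chr18	q	17200000	78077248	1
chr19	p	0	26500000	1
chr19	q	26500000	59128983	1
chr20	p	0	27500000	1
chr20	q	27500000	63025520	1
chr21	p	0	13200000	0
chr21	q	13200000	48129895	1
chr22	p	0	14700000	0
chr22	q	14700000	51304566	1
chrX	p	0	60600000	0
chrX	q	60600000	155270560	0
chrY	p	0	12500000	0
chrY	q	12500000	59373566	0
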