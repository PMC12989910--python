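symbol	chrom	start	end	on_panel
FUBP1	chr1	78409327	78444771	0
MDM4	chr1	204485511	204527248	0
H3F3A	chr1	226249412	226259703	1
MYCN	chr2	16080683	16087129	0
GLI2	chr2	121554866	121750229	0
IDH1	chr2	209100953	209119806	1
CTNNB1	chr3	41236328	41301587	1
PIK3CA	chr3	178866311	178952497	1
TACC3	chr4	1723217	1746905	1
FGFR3	chr4	1795039	1810599	1
PDGFRA	chr4	55095264	55164414	1
TERT	chr5	1253287	1295162	1
HIST1H3B	chr6	26031817	26032288	1
MYB	chr6	135502453	135540311	0
EGFR	chr7	55086725	55324313	1
CDK6	chr7	92234235	92465908	0
MET	chr7	116312459	116438440	0
SMO	chr7	128828713	128853662	1
KIAA1549	chr7	138515031	138665982	1
BRAF	chr7	140433812	140624564	1
FAM131B	chr7	143057165	143088204	0
FGFR1	chr8	38268656	38326352	1
TACC1	chr8	38585704	38710546	0
MYBL1	chr8	67474409	67525484	0
MYC	chr8	128748315	128753680	0
CDKN2A	chr9	21967751	21995300	1
CDKN2B	chr9	22002902	22009280	1
PTCH1	chr9	98205264	98279247	1
KLF4	chr9	110247133	110252047	1
TSC1	chr9	135766735	135820020	1
PTEN	chr10	89623195	89728532	1
MGMT	chr10	131265454	131565783	0
CCND1	chr11	69455873	69469242	0
CCND2	chr12	4382902	4414522	0
CDK4	chr12	58141510	58149796	0
MDM2	chr12	69201956	69239214	0
RB1	chr13	48877887	49056026	0
AKT1	chr14	105235686	105262088	1
IDH2	chr15	90626277	90645736	1
TSC2	chr16	2097990	2138713	1
TRAF7	chr16	2205024	2227458	1
TP53	chr17	7571720	7590868	1
NF1	chr17	29421945	29704695	1
PPM1D	chr17	58677544	58743037	0
SMARCA4	chr19	11071598	11172958	1
CIC	chr19	42788817	42799949	1
C19MC	chr19	54150000	54290000	0
SMARCB1	chr22	24129150	24176705	1
NF2	chr22	29999545	30094589	1
ATRX	chrX	76760356	77041719	1
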