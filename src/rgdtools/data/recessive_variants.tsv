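chrom	pos	ref	alt	clinvar_id	significance	condition	gene	cohort_variant
chr16	88810517	G	A	988047	Pathogenic	Adenine phosphoribosyltransferase deficiency (AR)	.	chr16:88810517:G>A
chr9	452071	C	T	2868856	Pathogenic	Autosomal recessive hyper-IgE syndrome (AR)	.	chr9:452071:C>T
chr15	42410958	G	C	195641	Pathogenic	Autosomal recessive limb-girdle muscular dystrophy type 2A (AR)	.	chr15:42410958:G>C
chr11	66511012	G	T	551439	Pathogenic	Bardet–Biedl syndrome (AR)	.	chr11:66511012:G>T
chr12	88049337	A	T	1071318	Pathogenic	Bardet–Biedl syndrome (AR) and nephronophthisis (AR)	.	chr12:88049337:A>T
chr1	230236716	C	T	873546	Pathogenic	Congenital disorder of glycosylation (AR)	.	chr1:230236716:C>T
chr16	68691842	T	G	800872	Pathogenic	Congenital hypotrichosis with juvenile macular dystrophy (AR)	.	chr16:68691842:T>G
chr7	50470090	G	A	2976771	Pathogenic	Deficiency of aromatic-l-amino-acid decarboxylase (AR)	.	chr7:50470090:G>A
chr2	232480717	C	A	1048794	Pathogenic	Distal arthrogryposis type 5D (AR)	.	chr2:232480717:C>A
chr19	35848087	C	T	56439	Pathogenic	Finnish congenital nephrotic syndrome (AR)	.	chr19:35848087:C>T
chr14	87939926	A	T	370392	Pathogenic	Galactosylceramide beta-galactosidase deficiency (AR)	.	chr14:87939926:A>T
chr1	155239937	G	A	1321421	Pathogenic	Gaucher disease (AR)	.	chr1:155239937:G>A
chr19	12893515	T	C	3015902	Pathogenic	Glutaric aciduria, type 1 (AR)	.	chr19:12893515:T>C
chr17	42911016	G	A	961497	Pathogenic	Glycogen storage disease due to glucose-6-phosphatase deficiency type IA (AR)	.	chr17:42911016:G>A
chr3	33068940	C	T	264673	Pathogenic	GM1 gangliosidosis type 2	.	chr3:33068940:C>T
chr9	101429754	C	T	218380	Pathogenic	Hereditary fructosuria (AR)	.	chr9:10142754:C>T
chr1	156875009	G	A	1323379	Pathogenic	Hereditary insensitivity to pain with anhidrosis (AR)	.	chr1:156875009:G>A
chr13	101073631	G	A	684708	Pathogenic	Hypotonia, infantile, with psychomotor retardation and characteristic facies 1 (AR)	.	chr13:101073631:G>A
chr5	148123905	C	T	959534	Pathogenic	Ichthyosis linearis circumflexa (AR)	.	chr5:14812 905:C>T
chr6	129314798	G	A	2735188	Pathogenic	LAMA2-related muscular dystrophy (AR)	.	chr6:129314798:G>A
chr1	68439640	T	A	2949504	Pathogenic	Leber congenital amaurosis (AR)	.	chr1:68439640:T>A
chr12	88055666	A	AT	156386	Pathogenic	Meckel syndrome, type 4 (AR)	.	chr12:88055666:A>AT
chr6	129316041	G	T	948070	Pathogenic	Merosin deficient congenital muscular dystrophy (AR)	.	chr6:129316041:G>T
chr1	197090004	G	A	157918	Pathogenic	Microcephaly 5, primary, autosomal recessive (AR)	.	chr1:197090004:G>A
chr8	89971175	G	A	2792660	Pathogenic	Microcephaly, normal intelligence and immunodeficiency (AR)	.	chr8:89971175:G>A
chr12	101749181	G	A	38429	Pathogenic	Mucolipidosis type II (AR)	.	chr12:101749181:G>A
chr16	88822614	C	T	2823297	Pathogenic	Mucopolysaccharidosis, MPS-IV-A (AR)	.	chr16:88822614:C>T
chr9	131512069	C	T	598282	Pathogenic	Muscular dystrophy-dystroglycanopathy (congenital with brain and eye anomalies), type A1 (AR)	.	chr9:131512069:C>T
chr12	88071890	T	TA	545704	Pathogenic	Nephronophthisis (AR)	.	chr12:88071890:T>TA
chr15	89321782	G	T	2843494	Pathogenic	Progressive sclerosing poliodystrophy (AR)	.	chr15:89321782:G>T
chr17	47945558	G	A	6524	Pathogenic	Pyridoxal phosphate-responsive seizures (AR)	.	chr17:47945558:G>A
chr2	71515752	G	A	290198	Pathogenic	Qualitative or quantitative defects of dysferlin (AR)	.	chr2:71515752:G>A
chr1	94000900	G	A	99458	Pathogenic	Severe early-childhood-onset retinal dystrophy (AR)	.	chr1:94000900:G>A
chr6	33173902	G	A	1455992	Pathogenic	Otospondylomegaepiphyseal dysplasia (AR)	.	chr6:33173902:G>A
chr1	215970661	T	TTGGACTCTGAAGGAATG	956100	Pathogenic	Usher syndrome (AR)	.	chr1:215970661:T>TTGGACTCTGAAGGAATG
chr13	51944170	C	T	312383	Pathogenic	Wilson disease (AR)	.	chr13:51944170:C>T
chr2	31373894	T	TG	2073968	Pathogenic	Xanthinuria type II (AR)	.	chr2:31373894:T>TG
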