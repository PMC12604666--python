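chrom	pos	ref	alt	clinvar_id	significance	condition	gene	cohort_variant
chr7	143332723	G	T	2950953	Pathogenic	Congenital myotonia, autosomal dominant form (AD)	.	chr7:143332723:G>T
chr2	165309366	T	C	976279	Pathogenic	Episodic ataxia (AD)	.	chr2:165309366:T>C
chr16	23629212	C	A	2 062838	Pathogenic	Familial cancer of breast (AD)	.	chr16:23629212:C>A
chr17	43071239	C	G	441389	Pathogenic	Hereditary breast ovarian cancer syndrome (AD)	.	chr17:43071239:C>G
chr1	45331503	G	A	406824	Pathogenic	Hereditary breast ovarian cancer syndrome (AD)	.	chr1:45331503:G>A
chr7	117665565	G	A	53929	Pathogenic	Hereditary pancreatitis (AD)	.	chr7:117665565:G>A
chr22	26026799	G	A	2506003	Pathogenic	Klippel–Feil syndrome (AD)	.	chr22:26026799:G>A
chr11	17396980	C	T	9098	Pathogenic	Leucine-induced hypoglycemia (AD)	.	chr11:17396980:C>T
chr22	20994728	G	C	984443	Pathogenic	Noonan syndrome (AD)	.	chr22:20994728:G>C
chr16	3757373	C	A	158358	Pathogenic	Rubinstein–Taybi syndrome due to CREBBP mutations (AD)	.	chr16:375373:C>A
chr2	165991694	G	A	1048587	Pathogenic	Severe myoclonic epilepsy in infancy (AD)	.	chr2:165991694:G>A
chr14	91314114	G	A	2841702	Pathogenic	Spinocerebellar ataxia type 40 (AD)	.	chr14:91314114:G>A
chr1	209788590	G	A	458682	Pathogenic	Van der Woude syndrome 1 (AD) and Popliteal pterygium syndrome (AD)	.	chr1:209788590:G>A
chr13	77903200	G	A	16639	Pathogenic	Waardenburg syndrome (AD)	.	chr13:77903200:G>A
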