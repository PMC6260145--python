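# Human IGH locus catalog, chromosome 14, GRCh38.p10.
# I-exon and S-region coordinates are the curated published mapping (1-based,
# inclusive). C-gene rows are approximate gene-body coordinates from public
# GRCh38 annotation, included for coding/non-coding pairing only.
name	chrom	start	end	kind
Imu	chr14	105861311	105862213	I_exon
Smu	chr14	105856501	105860500	S_region
Idelta	chr14	105847549	105847857	I_exon
Igamma3	chr14	105775023	105775702	I_exon
Sgamma3	chr14	105773001	105774000	S_region
Igamma1	chr14	105747322	105748299	I_exon
Sgamma1	chr14	105744501	105745500	S_region
Ialpha1.2	chr14	105711304	105711907	I_exon
Ialpha1.1	chr14	105712639	105712892	I_exon
Salpha1	chr14	105709501	105712500	S_region
Igamma2	chr14	105647803	105648549	I_exon
Sgamma2	chr14	105627501	105628500	S_region
Igamma4	chr14	105629000	105629500	I_exon
Sgamma4	chr14	105623001	105624000	S_region
Iepsilon	chr14	105605036	105605357	I_exon
Sepsilon	chr14	105602501	105604500	S_region
Ialpha2	chr14	105589300	105590300	I_exon
Salpha2	chr14	105589001	105591500	S_region
IGHM	chr14	105851437	105856218	C_gene
IGHD	chr14	105839587	105847843	C_gene
IGHG3	chr14	105766277	105772049	C_gene
IGHG1	chr14	105736343	105743071	C_gene
IGHA1	chr14	105703995	105708665	C_gene
IGHG2	chr14	105639559	105644800	C_gene
IGHG4	chr14	105615992	105621168	C_gene
IGHE	chr14	105597619	105601686	C_gene
IGHA2	chr14	105583731	105588395	C_gene
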