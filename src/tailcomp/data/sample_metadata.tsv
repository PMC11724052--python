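sample_name	replicate	species	organ	platform	project	accession	seq_data_link	seq_source	nonA_data	diffexp_data
ovary_Tent5bc_rep1	1	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS15941056	https://www.ebi.ac.uk/ena/browser/view/ERS15941056	Brouze et al.	Y	Y
ovary_Tent5bc_rep2	2	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS15941057	https://www.ebi.ac.uk/ena/browser/view/ERS15941057	Brouze et al.	Y	Y
ovary_WT_rep1	1	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS16372230	https://www.ebi.ac.uk/ena/browser/view/ERS16372230	Brouze et al.	Y	Y
ovary_WT_rep2_a	2	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS15941059	https://www.ebi.ac.uk/ena/browser/view/ERS15941059	Brouze et al.	Y	Y
ovary_WT_rep2_b	2	Mus musculus	ovary	ONT (DRS)	PRJEB46685	ERS5927539	https://www.ebi.ac.uk/ena/browser/view/ERS5927539	Brouze et al.	Y	Y
ovary_Tent5b_gfp_het_rep1	1	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS16372228	https://www.ebi.ac.uk/ena/browser/view/ERS16372228	Brouze et al.	Y	Y
ovary_Tent5b_gfp_het_rep2	2	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS16372248	https://www.ebi.ac.uk/ena/browser/view/ERS16372248	Brouze et al.	Y	Y
ovary_Tent5b_gfp_hom_rep1	1	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS15941063	https://www.ebi.ac.uk/ena/browser/view/ERS15941063	Brouze et al.	Y	Y
ovary_Tent5b_gfp_hom_rep2	2	Mus musculus	ovary	ONT (DRS)	PRJEB63526	ERS16372252	https://www.ebi.ac.uk/ena/browser/view/ERS16372252	Brouze et al.	Y	Y
testis_Tent5c_rep1	1	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846736	https://www.ebi.ac.uk/ena/browser/view/ERS5846736	Brouze et al.	Y	Y
testis_Tent5c_rep2	2	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846735	https://www.ebi.ac.uk/ena/browser/view/ERS5846735	Brouze et al.	Y	Y
testis_Tent5c_rep3	3	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846739	https://www.ebi.ac.uk/ena/browser/view/ERS5846739	Brouze et al.	Y	Y
testis_Tent5c_WT_rep1	1	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846734	https://www.ebi.ac.uk/ena/browser/view/ERS5846734	Brouze et al.	Y	Y
testis_Tent5c_WT_rep2	2	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846733	https://www.ebi.ac.uk/ena/browser/view/ERS5846733	Brouze et al.	Y	Y
testis_Tent5c_WT_rep3	3	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846741	https://www.ebi.ac.uk/ena/browser/view/ERS5846741	Brouze et al.	Y	Y
testis_Tent5d_rep1	1	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846730	https://www.ebi.ac.uk/ena/browser/view/ERS5846730	Brouze et al.	Y	Y
testis_Tent5d_rep2	2	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5846732	https://www.ebi.ac.uk/ena/browser/view/ERS5846732	Brouze et al.	Y	Y
testis_Tent5d_WT_rep1	1	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5465457	https://www.ebi.ac.uk/ena/browser/view/ERS5465457	Brouze et al.	Y	Y
testis_Tent5d_WT_rep2	2	Mus musculus	testis	ONT (DRS)	PRJEB45063	ERS5465455	https://www.ebi.ac.uk/ena/browser/view/ERS5465455	Brouze et al.	Y	Y
Mouse_testis_spermatids_WT_16	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425435	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425435	this work	n	Y
Mouse_testis_spermatids_TENT5C_KO_17	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425436	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425436	this work	n	Y
Mouse_testis_spermatids_WT_18	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425437	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425437	this work	n	Y
20170221_FamC_ES	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425438	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425438	this work	n	Y
20170221_FamC_RS	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425439	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425439	this work	n	Y
20170221_WT_ES	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425440	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425440	this work	n	Y
20170221_WT_RS	1	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425441	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425441	this work	n	Y
20170223_FamC_ES	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425442	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425442	this work	n	Y
20170223_FamC_RS	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425443	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425443	this work	n	Y
20170223_WT_ES	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425444	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425444	this work	n	Y
20170223_WT_RS	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425445	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425445	this work	n	Y
20170406_FamC_ES	3	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425446	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425446	this work	n	Y
20170406_FamC_RS	3	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425447	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425447	this work	n	Y
20170406_WT_ES	3	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425448	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425448	this work	n	Y
20170406_WT_RS	3	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425449	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425449	this work	n	Y
Mouse_testis_spermatids_TENT5C_KO_19	2	Mus musculus	testis	Illumina	PRJNA1141133	GSM8425450	https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSM8425450	this work	n	Y
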