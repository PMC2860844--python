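pdb_code	description	sequence	length	distinct
1FG2	LCMV peptidic epitope (gp33)	LAVYNFATC	9	1
1JPF	LCMV peptidic epitope (gp276)	SGVENPGGYCL	11	1
1JPG	LCMV peptidic epitope (np396)	FQPQNGQFI	9	1
1INQ	MHC class I H13a minor histocompatibility peptide	SSVVGVWYL	9	1
1JUF	Minor histocompatibility antigen peptide (H13b) P4(Val/Ile)	SSVIGVWYL	9	1
1N3N	Mycobacterial hsp60 epitope	SALQNAASIA	10	1
1QLF	Sendai NP324-332 (gly327 replaced by o-glcnac serine)	FAPSNYPAL	9	1
1S7U	LCMV-derived immunodominant peptide (gp33); also 2F74/1FFN/1N5A	KAVYNFATM	9	1
1S7V	LCMV-derived (gp33) index peptide - escape variant	KAVYNLATM	9	1
1S7W	LCMV-derived (gp33) index peptide - escape variant	KALYNFATM	9	1
1S7X	LCMV-derived (gp33) index peptide - escape variant	KAVFNFATM	9	1
1FFO	gp33 synthetic peptide with substitution K1A/C9M	AAVYNFATM	9	1
1FFP	gp33 synthetic peptide with substitution K1S/C9M	SAVYNFATM	9	1
1WBX	Peptide from influenza A (pr8) HA468-477	SQLKNNAKEI	10	1
1WBY	Peptide from influenza A (pr8) PA224-233; also 1YN6	SSLENFRAYV	10	1
1YN7	Mutated peptide (R7A) from RNA polymerase subunit P2	SSLENFAAYV	10	1
1ZHB	9-mer peptide from dopamine beta-monooxygenase	KALYNYAPI	9	1
1BZ9	Synthetic peptide (P1027)	FAPGVFPYM	9	1
1CE6	Sendai virus nucleoprotein peptide (NP324-332)	FAPGNYPAL	9	1
2VE6	Altered peptide of Sendai virus (photocleavable peptide)	FAPGNYPAL	9	1
2CII	Sendai virus nucleoprotein epitope (incomplete epitope density)	FAPGNYPAL	9	0
2ZOK	9-meric peptide from spike glycoprotein	ASLWNGPHL	9	1
2ZOL	9-meric peptide from spike glycoprotein - mutation W4S	ASLSNGPHL	9	1
1HOC	Influenza virus peptide NP366-374	ASNENMETM	9	1
3CPL	Influenza virus peptide NP366-374 with substitution M6A	ASNENAETM	9	1
3BUY	Epitope of PB1-F2	LSLRNPILV	9	1
3CC5	Nonameric peptide from melanocyte protein Pmel 17	KVPRNQDWL	9	1
3CCH	Nonameric peptide murine gp100	EGSRNQDWL	9	1
3CH1	Nonameric peptide chimeric gp100	EGPRNQDWL	9	1
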