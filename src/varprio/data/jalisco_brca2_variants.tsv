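hgvs_cdna	hgvs_protein	rsid	carriers_bc	carriers_oc	clinical_classification	clinvar_aggregate	clinvar_review
c.3188A>G	p.Gln1063Arg	rs775030825	1	0	VUS	Uncertain significance;Likely benign	Conflicting classifications of pathogenicity (guidelines-based)
c.3264dup	p.Gln1089fs	rs80359380	3	0	Pathogenic	Pathogenic	Reviewed by expert panel, guidelines-based
c.5073dup	p.Trp1692fs	rs80359479	1	1	Pathogenic	Pathogenic	Reviewed by expert panel, guidelines-based
c.6275_6276del	p.Leu2092fs	rs11571658	2	0	Pathogenic	Pathogenic;Likely pathogenic	Reviewed by expert panel, guidelines-based
c.6415_6416delinsAT	p.Glu2139Leu	rs1064795067	1	0	VUS	Uncertain significance;Likely benign	Conflicting classifications of pathogenicity (criteria provided, single submitter, guidelines-based)
c.9235delG	p.Val3079fs	rs397507422	1	0	Pathogenic	Pathogenic;Likely pathogenic	Reviewed by expert panel, guidelines-based
c.9364G>C	p.Ala3122Pro	rs587782313	2	0	Probably pathogenic	Uncertain significance;Likely pathogenic	Conflicting classifications of pathogenicity (criteria provided, single submitter, guidelines-based)
c.9455A>G	p.Glu3152Gly	rs80359219	1	0	VUS	Uncertain significance;Likely benign	Conflicting classifications of pathogenicity (criteria provided, single submitter, guidelines-based)
c.9560A>G	p.Asn3187Ser	rs1329182873	1	0	VUS	Uncertain significance	Multiple submitters, no conflicts, guidelines-based
c.9812T>C	p.Leu3271Ser		1	0	VUS	Uncertain significance	Multiple submitters, no conflicts, guidelines-based
c.1838T>G	p.Leu613Arg	rs587780646	0	1	VUS	Uncertain significance;Likely benign	Conflicting classifications of pathogenicity (single submitter, guidelines-based)
c.3481_3482dup	p.Asp1161fs	rs878853569	0	1	Pathogenic	Pathogenic	Reviewed by expert panel, guidelines-based
c.8839G>T	p.Glu2947Ter	rs398122715	0	1	Pathogenic	Pathogenic	Reviewed by expert panel, guidelines-based
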