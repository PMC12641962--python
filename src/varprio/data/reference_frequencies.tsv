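variant_key	source_label	k2	n2	kind
rs587782313	Portugal OC	1	95	cohort
rs587782313	gnomAD	65	1401414	database
rs80359380	Spain BC	10	118	cohort
rs80359380	Mexico TNBC	1	387	cohort
rs80359380	gnomAD	7	573348	database
rs398122715	gnomAD	1	78578	database
rs587780646	Mexico BC	1	51	cohort
rs587780646	gnomAD	18	1395472	database
rs1329182873	gnomAD	2	595622	database
c.9812T>C	gnomAD	2	595664	database
rs397507422	Mexico BC/OC	1	92	cohort
rs397507422	gnomAD	7	1400962	database
rs878853569	Brazil BC	1	12	cohort
rs878853569	gnomAD	1	595546	database
rs80359479	Brazil BC	1	248	cohort
rs80359479	gnomAD	6	264690	database
rs775030825	gnomAD	3	590348	database
rs11571658	Canada OC	1	1342	cohort
rs11571658	Mexico BC	1	3842	cohort
rs11571658	gnomAD	105	1394404	database
rs80359219	gnomAD	8	595596	database
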