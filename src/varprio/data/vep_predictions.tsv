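variant_key	sift_score	polyphen_score	sift_label	polyphen_label
rs775030825	0.02	0.35	Deleterious	Benign
rs80359380
rs80359479
rs11571658
rs1064795067	0	0.738	Deleterious	Possibly damaging
rs397507422
rs587782313	0	0.936	Deleterious	Probably damaging
rs80359219	0.02	0.027	Deleterious	Benign
rs1329182873	0.22	0.007	Tolerated	Benign
c.9812T>C
rs587780646	0.01	0.357	Deleterious	Benign
rs878853569
rs398122715
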