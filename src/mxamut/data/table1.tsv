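protein_change	cancer_type	source_id
p.S134L	colorectal cancer	CRC-A
p.N491K	colorectal cancer	CRC-A
p.R522C	colorectal cancer	CRC-A
p.T651M	colorectal cancer	CRC-A
p.R654Q	colorectal cancer	CRC-A
p.V263M	colorectal cancer	CRC-B
p.Y538C	colorectal cancer	CRC-B
p.S572Y	colorectal cancer	CRC-B
p.R655C	colorectal cancer	CRC-A
p.R655C	colorectal cancer	CRC-B
p.T651M	head and neck squamous cell carcinoma	HNSCC-A
p.T27S	follicular lymphoma	FL-A
p.L95P	cutaneous squamous cell carcinoma	CSCC-A
p.P96S	cutaneous squamous cell carcinoma	CSCC-A
p.P218S	cutaneous squamous cell carcinoma	CSCC-A
p.G540D	mantle cell lymphoma	MCL-A
p.L643V	mantle cell lymphoma	MCL-A
p.V449G	embryonal rhabdomyosarcoma	ERMS-A
p.G392V	renal cell carcinoma	RCC-A
p.K326N	prostate cancer	PC-A
p.R310S	lung adenocarcinoma	LUAD-A
p.E632K	melanoma	MEL-A
p.R649W	medulloblastoma	MB-A
p.L619I	ovarian carcinoma	OV-A
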