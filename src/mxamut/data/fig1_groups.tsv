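position	residue	category
95	L	conserved_both
96	P	conserved_both
218	P	conserved_both
263	V	conserved_both
619	L	conserved_both
632	E	conserved_both
643	L	conserved_both
134	S	overall_considerable
310	R	overall_considerable
392	G	overall_considerable
538	Y	overall_considerable
326	K	mx_only
449	V	mx_only
572	S	mx_only
649	R	mx_only
654	R	mx_only
27	T	none
491	N	none
522	R	none
540	G	none
651	T	none
655	R	none
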