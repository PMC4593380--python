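mutation	domain	burial	interactions	interface_candidate
L95P	G domain	buried	hydrophobic:L87:intra;hydrophobic:V93:intra;hydrophobic:L107:intra;hydrophobic:L109:intra;hydrophobic:I143:intra;hydrophobic:L164:intra	0
P96S	G domain	exposed		0
S134L	G domain	exposed		0
P218S	G domain	exposed		0
V263M	G domain	buried	hydrophobic:I223:intra;hydrophobic:L246:intra;hydrophobic:V264:intra;hydrophobic:V268:intra	0
R310S	G domain	exposed		0
K326N	G domain	exposed	hydrogen_bond:K273:intra;salt_bridge:E330:intra	0
G392V	Stalk	exposed	hydrophobic:V449:inter	0
V449G	Stalk	buried	hydrophobic:G392:inter	0
N491K	Stalk	exposed	hydrogen_bond:D385:intra	0
R522C	Stalk	exposed	salt_bridge:E466:intra;salt_bridge:E467:intra;salt_bridge:E518:intra	0
L619I	Stalk	buried	hydrophobic:L498:intra;hydrophobic:M616:intra;hydrophobic:L629:intra	0
E632K	Hinge 1	buried	salt_bridge:R640:intra	0
L643V	BSE	exposed	hydrophobic:L357:intra	0
R649W	BSE	exposed		1
T651M	BSE	exposed		1
R654Q	BSE	buried	salt_bridge:D478:inter	0
R655C	BSE	exposed		1
T27S	N'-loop	exposed		0
Y538C	L4	exposed		0
G540D	L4	exposed		0
S572Y	L4	exposed		0
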