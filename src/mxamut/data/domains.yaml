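# Human MxA domain architecture (UniProt P20591 numbering, 662 residues).
# The BSE is discontiguous (three helices: N-terminal, middle, C-terminal);
# the Stalk is split in sequence by the disordered L4 loop; Hinge 1 is the
# two-loop connector between Stalk and the C-terminal BSE helix.
# Boundaries are calibrated to the published per-site domain placement of
# the 22 cancer-associated mutation positions.
protein_length: 662
segments:
  - {name: "N'-loop", start: 1, end: 43}
  - {name: "BSE", start: 44, end: 68}
  - {name: "G domain", start: 69, end: 340}
  - {name: "BSE", start: 341, end: 364}
  - {name: "Hinge 1", start: 365, end: 371}
  - {name: "Stalk", start: 372, end: 532}
  - {name: "L4", start: 533, end: 572}
  - {name: "Stalk", start: 573, end: 625}
  - {name: "Hinge 1", start: 626, end: 638}
  - {name: "BSE", start: 639, end: 662}
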