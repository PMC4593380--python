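# Classifier configuration: polarity categories, side-chain volumes and
# rule thresholds for the four-tier impact verdict.

# Polarity categories as used in the impact summary (distinct from the
# conservation residue-group scheme: e.g. Y is "polar" here but grouped
# with the weak/nonpolar residues for conservation scoring).
polarity:
  nonpolar: [L, V, M, I, W, A, F]
  weak_polar: [C]
  polar: [S, T, N, Q, Y]
  positive: [K, R, H]
  negative: [D, E]
  special: [G, P]

# Side-chain capability and steric sets used by the rules.
hbond_capable: [S, T, N, Q, Y, H, K, R, D, E, W]
bulky_hydrophobes: [W, F, M]

# Mean residue volumes (A^3), Zamyatnin-style standard table.
volumes:
  A: 88.6
  R: 173.4
  N: 114.1
  D: 111.1
  C: 108.5
  Q: 143.8
  E: 138.4
  G: 60.1
  H: 153.2
  I: 166.7
  L: 166.7
  K: 168.6
  M: 162.9
  F: 189.9
  P: 112.7
  S: 89.0
  T: 116.1
  W: 227.8
  Y: 193.6
  V: 140.0

# Volume gain (A^3) above which a nonpolar->nonpolar substitution in a
# hydrophobic core is called moderate rather than very moderate.
volume_gain_threshold: 15.0

# Surface sites on the C-terminal BSE helix annotated as candidate
# protein-partner interfaces (site annotation, not computed geometry).
interface_candidate_sites: [649, 651, 655]
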