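# Distance criteria and atom-typing tables for interaction detection,
# SASA parameters, and reference-structure routing.

criteria:
  hbond_min: 2.7     # A; donor-acceptor heavy-atom window (distance-only)
  hbond_max: 3.5
  contact_max: 4.0   # A; salt bridges and hydrophobic contacts

# Charged side-chain group atoms (plus chain termini handled in code:
# first-residue backbone N positive, OXT negative).
positive_atoms:
  ARG: [NE, NH1, NH2]
  LYS: [NZ]
  HIS: [ND1, NE2]
negative_atoms:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]

# Hydrophobic side-chain carbons. Tyr contributes its ring carbons only
# (config-exposed); the Cys sulfur is excluded.
hydrophobic_atoms:
  ALA: [CB]
  VAL: [CB, CG1, CG2]
  LEU: [CB, CG, CD1, CD2]
  ILE: [CB, CG1, CG2, CD1]
  MET: [CB, CG, CE]
  PHE: [CB, CG, CD1, CD2, CE1, CE2, CZ]
  TRP: [CB, CG, CD1, CD2, CE2, CE3, CZ2, CZ3, CH2]
  PRO: [CB, CG, CD]
  CYS: [CB]
tyr_ring_atoms: [CG, CD1, CD2, CE1, CE2, CZ]
include_tyr_ring: true

# Van der Waals radii (A) by element for SASA.
vdw_radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
default_radius: 1.70

sasa:
  probe_radius: 1.4
  n_points: 960

burial:
  relative_sasa_threshold: 0.25
  # Theoretical maximum accessible surface areas (A^2) per residue type
  # (Tien et al. 2013, theoretical values).
  reference_areas:
    ALA: 129.0
    ARG: 274.0
    ASN: 195.0
    ASP: 193.0
    CYS: 167.0
    GLU: 223.0
    GLN: 225.0
    GLY: 104.0
    HIS: 224.0
    ILE: 197.0
    LEU: 201.0
    LYS: 236.0
    MET: 224.0
    PHE: 240.0
    PRO: 159.0
    SER: 155.0
    THR: 172.0
    TRP: 285.0
    TYR: 263.0
    VAL: 174.0

# Reference-structure routing: which deposited MxA structure carries each
# region at the best resolution. Switch I (95, 96) is ordered only in the
# nucleotide-bound G-domain structure.
reference_route:
  switch_i_positions: [95, 96]
  switch_i_structure: 4P4S
  domain_structures:
    G domain: 4P4U
    Stalk: 3LJB
    BSE: 3SZR
    Hinge 1: 3SZR
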