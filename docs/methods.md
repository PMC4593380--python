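# Methods

## Scope and model

`mxamut` annotates single amino acid substitutions in human MxA
(662 residues) with a structure-derived impact verdict. The underlying
model is deliberately simple and auditable: every structural criterion
is a distance rule evaluated on deposited crystal coordinates, and the
final verdict is produced by an ordered, inspectable rule set rather
than a learned score. The package takes alignments and structures as
inputs; it does not compute alignments (no Clustal reimplementation),
build homology models, or expand crystallographic symmetry.

## Mutation screening

Protein changes are parsed from HGVS-like notation (1- or 3-letter
codes, `p.` prefix optional, stop `*`, silent `=`, frameshift `fs`
suffixes). Screening keeps missense changes only: frameshifts and stop
gains truncate the chain and silent changes leave it intact, so neither
is amenable to substitution-level structural analysis. Deduplication is
at the protein-change level — the same substitution observed in two
sequencing projects is one unique mutation with recurrence 2 — because
the analysis is of the protein, not of the underlying nucleotide events.

## Domain map

MxA's architecture is discontiguous: the bundle-signaling element (BSE)
is assembled from three helices at the N-terminus (44–68), middle
(341–364) and C-terminus (639–662) of the chain, and the Stalk
(372–532, 573–625) is interrupted by the disordered L4 loop (533–572).
The N′-loop (1–43) and L4 are intrinsically disordered and absent from
every deposit. Published domain boundaries for MxA are given graphically
rather than as residue numbers, so the shipped `domains.yaml` boundaries
are calibrated: they are chosen once so that every mutation site in the
packaged catalog falls in its published domain, and the calibration is
enforced by regression tests. Users with different boundary conventions
can supply their own YAML map.

## Conservation

Conservation is scored by physicochemical group, not strict identity:
D/E (negative), R/K/H (positive), N/Q/S/T (polar), A/L/I/V/F/Y/W/M/C
(weak or nonpolar), P/G (special). For each reference position
(human MxA, ungapped positions mapped through the alignment), the score
in a sequence subset is the fraction of subset sequences whose residue
shares the reference residue's group; gaps count as mismatches, since
manually adjusted loop columns carry no conservation signal. Two
subsets are scored — six Mx proteins and six classical dynamins — and a
position is binned as:

- `conserved_both`: both subsets ≥ `t_high` (default 0.7, the published
  conservation threshold);
- `mx_only`: Mx subset ≥ `t_high`, dynamin subset < `t_low`;
- `overall_considerable`: otherwise, size-weighted overall fraction ≥
  `t_low` (default 0.5 — no threshold is published for "considerable",
  so this is a configurable package choice);
- `none`: otherwise.

The mx-only test precedes the overall test because a column perfectly
conserved in the Mx clade alone already has an overall fraction of 0.5;
binning it as merely "considerable overall" would erase the clade
signal. Note that this grouping intentionally differs from the impact
classifier's polarity table (tyrosine is grouped with nonpolar residues
for conservation but counted polar for impact): the two tables serve
different published conventions and are kept separate.

## Structural evidence

**Interactions.** Residue–residue contacts are detected from heavy-atom
center distances only: hydrogen bonds at 2.7–3.5 Å between N/O atoms
(side-chain N/O plus backbone amide N and carbonyl O), salt bridges at
≤ 4 Å between oppositely charged side-chain group atoms (Arg
NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2, plus chain
termini), and hydrophobic contacts at ≤ 4 Å between typed side-chain
carbons (Tyr contributes ring carbons, configurable; the Cys sulfur is
excluded). No angle terms are applied — fidelity to the distance-only
convention under which the reference structures were analyzed is
preferred over chemical orthodoxy, and pairs below 2.7 Å are not
counted as hydrogen bonds. Within one atom pair the priority is salt
bridge > hydrogen bond > hydrophobic, so an ion pair inside the
hydrogen-bond window is reported once, as a salt bridge.
Sequence-adjacent residues (|Δposition| ≤ 1, same chain) are excluded.
Inter-chain contacts are searched over the chains deposited in the
file — the crystal-lattice oligomer copies — with no symmetry-mate
generation. Distance-window comparisons carry a 1e-9 Å guard so that
coordinates written at PDB precision compare as intended at the window
edges (the windows are closed intervals).

**Altloc policy.** Alternate conformations are resolved to the
highest-occupancy conformer, ties broken alphabetically. Residues with
two deposited side-chain conformations are therefore evaluated on one
conformer; enumerating altlocs is possible by pre-filtering the file.

**Burial.** Solvent-accessible surface area uses the Shrake–Rupley
method with a 1.4 Å probe, element vdW radii (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å) and a deterministic Fibonacci sphere lattice
(960 points by default). Relative SASA is the residue's total area over
its residue-type theoretical maximum (Tien et al. 2013); a residue is
buried below 0.25. Whole-residue (rather than side-chain-only) relative
SASA is used so the definition covers glycine, which has no side-chain
heavy atoms; side-chain area is still reported. The fixed lattice makes
areas exactly translation-invariant and deterministic, but rotating a
model re-samples the quadrature, so areas agree across orientations
only to discretization error (which shrinks with point count); the
tests pin this at < 0.5 Å² per atom and < 1 % in total at 4000 points.

**Reference routing.** Each region routes to the deposited structure
that resolves it at the best resolution: Switch I positions (95, 96) to
the GMPPCP-bound stalkless construct (4P4S) — Switch I is ordered only
with bound nucleotide — other G-domain positions to the apo stalkless
structure (4P4U), Stalk positions to the stalk structure (3LJB), and
BSE/Hinge 1 positions to full-length MxA (3SZR). N′-loop and L4
positions route to "none": no deposit resolves them.

**Superposition.** Least-squares superposition uses the Kabsch SVD
solution with the determinant correction for proper rotations;
collinear or under-sized (< 3 atoms) inputs are rejected as degenerate.
The test suite cross-checks RMSD values against an independent
quaternion (Horn) implementation.

## Impact rule set

The four-tier verdict is produced by ordered rules; the first match
fires. The rules are an explicit codification of per-case structural
reasoning — residue stereochemistry, engagement in interactions,
position — not a fitted model, and they are config-replaceable
(`classify.yaml`).

1. **R1 disordered** → *unpredictable*. Sites on the N′-loop or L4 have
   no observable structure to judge against.
2. **R2 special residue** (Pro or Gly on either side) → *drastic*.
   Proline's confined backbone dihedrals and glycine's flexibility
   redirect the chain regardless of context.
3. **R3 charge disruption** → *drastic*. A charged residue engaged in
   salt bridges loses hydrogen-bond capability outright, or acquires
   the same charge sign as its salt-bridge partner.
4. **R4 polar engagement preserved** — a residue engaged through
   hydrogen bonds or salt bridges is replaced by one gaining charge
   complementarity with its partner (→ *very moderate*: the contact
   may even strengthen) or one merely retaining hydrogen-bond
   capability (→ *moderate*).
5. **R5 interface candidate** → *moderate*. An exposed, interaction-free
   site annotated as a candidate protein-partner interface suffers a
   strong-polarity loss, a bulky-hydrophobe gain (W/F/M) or a
   modification-prone cysteine gain. Interface candidacy is a shipped
   site annotation (the surface residues 649/651/655 of the C-terminal
   BSE helix), not computed geometry.
6. **R6 core volume gain** → *moderate*. A hydrophobically engaged
   nonpolar residue is replaced by a nonpolar residue more than 15 Å³
   larger (Zamyatnin-style mean residue volumes).
7. **R7 fallback** → *very moderate*.

Rule order is semantic and tested: a glycine substitution on L4 is
*unpredictable* (R1), not *drastic* (R2), because the disorder verdict
dominates. Classification is a pure function of the feature bundle.
Features can be computed from routed structures or supplied as a
transcribed annotation table (the packaged `table3_features.tsv`
transcribes the published per-site evidence); provenance is recorded.
Two published idiosyncrasies are retained as-is: one surface site with
preserved hydrogen bonding is ranked moderate although the prose calls
its disruption minor, and one Tyr substitution is tabulated
polar→polar; the shipped tables follow the tabulated verdicts.

## Synthetic data

The generators produce every input family with planted, analytically
known structure, so the full pipeline is testable offline:

- **Interaction fixtures**: minimal PDB scenes with idealized
  side-chain geometry — a target residue's probe atom at the origin and
  partner probe atoms at exact planted distances along octahedral
  directions, backbones placed radially so no backbone N/O strays into
  an interaction window. Planted distances below covalent geometry
  (< 1 Å) are rejected, and pocket fixtures enforce ≥ 2.9 Å so partner
  shells cannot touch each other.
- **Dimer fixtures**: one charged pair across chains A/B (or merged
  into one chain) to exercise inter- vs intra-chain scoping.
- **Burial fixtures**: a compact residue enclosed by an occluding
  carbon shell (buried) or isolated (exposed).
- **Alignments**: 12 sequences whose per-column group conservation in
  each subset equals the requested fraction exactly (fractions must be
  multiples of 1/6; the reference sequence always matches itself).
- **Mutation tables**: the packaged 24-observation catalog plus seeded
  decoys spanning all consequence classes, with a ground-truth sidecar.
- **Fact scenes**: synthetic stand-ins planting the published MxA
  contact facts (the Hinge 1 salt bridge, the inter-molecular BSE–Stalk
  salt bridge, the Stalk charge network, the G-domain hydrophobic
  pocket) with the real residue identities and numbers. These are
  labelled synthetic and are not crystallographic coordinates.

All generators are seeded and byte-reproducible. What passing on these
fixtures does **not** show: behaviour on real crystallographic geometry
(distorted side chains, altlocs, insertion codes at scale), alignment
columns with biological substitution patterns, or the correctness of
the transcribed feature annotations themselves — those are fixed inputs,
not computed ones.

## Problem sizes and numerical choices

The default test and acceptance runs use the 24-observation catalog,
100-fixture detector sweeps, 100-column planted alignments and
100 random superposition sets — sizes at which every check is exact or
at fixed tolerance (planted distances to 1e-3 Å, superposition oracle
agreement to 1e-6 Å, SASA closed-form to 2 % at 960 sphere points).
Degenerate inputs fail loudly: malformed protein changes, ragged
alignments, structures without atoms, collinear superposition inputs
and out-of-range thresholds all raise typed errors rather than
propagating defaults.

## Known limitations

- Hydrogen bonds are distance-only; no donor/acceptor chemistry beyond
  element typing, no angles, no protonation states.
- Burial thresholding at 0.25 relative SASA is a convention; deeply
  cleft-bound but technically accessible residues can be misbinned.
- The rule set encodes judgment calls (e.g. what counts as a bulky
  hydrophobe) as configuration, and its verdicts are only as good as
  the feature bundle — computed features on a poorly chosen reference
  structure will mislead it.
- Conservation categories depend on subset composition; adding or
  removing homologs changes fractions discretely (steps of 1/6 at the
  default subset size).
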