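"""Per-position conservation over an Mx/dynamin multiple sequence alignment.

Conservation is scored by residue *group* rather than strict identity:
two residues count as conserved if they share a physicochemical group
(negative D/E; positive R/K/H; polar N/Q/S/T; weak or nonpolar
A/L/I/V/F/Y/W/M/C; special P/G). A position is scored separately over
the Mx-protein subset and the dynamin subset and then binned into one
of four categories:

* ``conserved_both`` — conserved (≥ t_high) in Mx proteins and dynamins;
* ``overall_considerable`` — considerable conservation over the full set;
* ``mx_only`` — conserved in Mx proteins but not in dynamins;
* ``none`` — no conservation.

Positions are reference-sequence positions (human MxA, UniProt P20591
by default), mapped through the alignment gap structure. Gaps count as
mismatches: manually adjusted loop regions are non-conserved by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pathlib import Path

from Bio import AlignIO

#: amino acid -> physicochemical group for conservation scoring
RESIDUE_GROUPS: dict[str, str] = {
    **{aa: "negative" for aa in "DE"},
    **{aa: "positive" for aa in "RKH"},
    **{aa: "polar" for aa in "NQST"},
    **{aa: "weak_nonpolar" for aa in "ALIVFYWMC"},
    **{aa: "special" for aa in "PG"},
}

#: default alignment subsets (Mx proteins vs classical dynamins)
MX_SET = ("hsMxA", "hsMxB", "mmMx1", "mmMx2", "ggMx", "drMxA")
DYNAMIN_SET = ("hsDyn1", "hsDyn2", "hsDyn3", "dmDynamin", "ceDynamin", "scDNM1")

CATEGORIES = ("conserved_both", "overall_considerable", "mx_only", "none")


def read_alignment(path: str | Path, fmt: str | None = None) -> dict[str, str]:
    """Read an aligned FASTA or Clustal file as {id: aligned sequence}.

    Sequences are upper-cased; gap characters ('.', '-') normalized to
    '-'. All sequences must share one aligned length.
    """
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal", ".clw") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    seqs = {rec.id: str(rec.seq).upper().replace(".", "-") for rec in aln}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return seqs


@dataclass(frozen=True)
class AlignmentColumnMap:
    """Gap-aware map from reference-sequence positions to alignment columns."""

    reference_id: str
    columns: tuple[int, ...]  # columns[i] = 0-based column of reference position i+1

    @classmethod
    def from_alignment(cls, seqs: dict[str, str], reference_id: str) -> "AlignmentColumnMap":
        if reference_id not in seqs:
            raise KeyError(f"reference {reference_id!r} not in alignment")
        cols = tuple(i for i, c in enumerate(seqs[reference_id]) if c != "-")
        return cls(reference_id=reference_id, columns=cols)

    def column_of(self, position: int) -> int:
        """0-based alignment column of a 1-based reference position."""
        if not 1 <= position <= len(self.columns):
            raise ValueError(f"reference position {position} outside [1, {len(self.columns)}]")
        return self.columns[position - 1]


def group_conservation(
    column: dict[str, str],
    reference_residue: str,
    subset: tuple[str, ...],
    scheme: dict[str, str] | None = None,
) -> float:
    """Fraction of subset sequences sharing the reference residue's group.

    Gaps and unknown letters count as mismatches. The reference residue
    must be ungapped at the column.
    """
    scheme = scheme or RESIDUE_GROUPS
    if not subset:
        raise ValueError("subset must be non-empty")
    ref_group = scheme.get(reference_residue.upper())
    if ref_group is None:
        raise ValueError(f"reference residue {reference_residue!r} is gapped or non-standard")
    hits = sum(1 for sid in subset if scheme.get(column.get(sid, "-")) == ref_group)
    return hits / len(subset)


def categorize_position(
    mx_fraction: float,
    dynamin_fraction: float,
    t_high: float = 0.7,
    t_low: float = 0.5,
    mx_n: int = len(MX_SET),
    dynamin_n: int = len(DYNAMIN_SET),
) -> str:
    """Bin a position into one of the four conservation categories.

    The overall fraction is the size-weighted mean of the two subset
    fractions.
    """
    for name, t in (("t_high", t_high), ("t_low", t_low)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    all_fraction = (mx_fraction * mx_n + dynamin_fraction * dynamin_n) / (mx_n + dynamin_n)
    if mx_fraction >= t_high and dynamin_fraction >= t_high:
        return "conserved_both"
    # mx-only takes precedence: a column fully conserved in Mx proteins
    # alone has overall fraction 0.5 and is not "considerable overall"
    if mx_fraction >= t_high and dynamin_fraction < t_low:
        return "mx_only"
    if all_fraction >= t_low:
        return "overall_considerable"
    return "none"


@dataclass
class ConservationProfile:
    """Per-position conservation fractions and category for one alignment."""

    reference_id: str
    positions: dict[int, dict] = field(default_factory=dict)

    def category(self, position: int) -> str:
        return self.positions[position]["category"]


def profile_positions(
    seqs: dict[str, str],
    positions: list[int],
    reference_id: str = "hsMxA",
    mx_set: tuple[str, ...] = MX_SET,
    dynamin_set: tuple[str, ...] = DYNAMIN_SET,
    t_high: float = 0.7,
    t_low: float = 0.5,
    scheme: dict[str, str] | None = None,
) -> ConservationProfile:
    """Score and categorize a list of reference positions on an alignment."""
    colmap = AlignmentColumnMap.from_alignment(seqs, reference_id)
    profile = ConservationProfile(reference_id=reference_id)
    for pos in positions:
        col_idx = colmap.column_of(pos)
        column = {sid: s[col_idx] for sid, s in seqs.items()}
        ref_res = column[reference_id]
        mx_frac = group_conservation(column, ref_res, mx_set, scheme)
        dyn_frac = group_conservation(column, ref_res, dynamin_set, scheme)
        profile.positions[pos] = {
            "residue": ref_res,
            "mx_fraction": mx_frac,
            "dynamin_fraction": dyn_frac,
            "category": categorize_position(
                mx_frac, dyn_frac, t_high, t_low, len(mx_set), len(dynamin_set)
            ),
        }
    return profile
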