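"""Mutation catalog: parse, screen and tabulate protein-level cancer mutations.

Input tables emulate COSMIC-style exports: one row per observed mutation
with an HGVS-like protein change (``p.L95P``, ``Leu95Pro``, ``p.R655*``,
``p.K83fs``), a cancer-type label and a source/sample identifier.
Screening keeps only missense changes — frameshifts and stop gains
truncate the chain outright and silent changes leave the protein intact,
so neither is informative for structure-level impact analysis.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "TER": "*",
}

_CHANGE_RE = re.compile(
    r"^(?:p\.)?"
    r"(?P<ref>[A-Za-z]{1,3})"
    r"(?P<pos>\d+)"
    r"(?P<rest>.*)$"
)


class ProteinChangeError(ValueError):
    """Raised when an HGVS-like protein change cannot be parsed."""


@dataclass(frozen=True)
class MutationRecord:
    """One observed protein-level mutation.

    ``consequence`` is derived from the change notation: missense,
    silent, nonsense (stop gain), frameshift, or other.
    """

    raw_change: str
    ref_aa: str
    position: int
    alt_aa: str
    consequence: str
    cancer_type: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ProteinChangeError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA1:
            raise ProteinChangeError(f"reference residue {self.ref_aa!r} not a standard amino acid")
        if self.consequence == "missense":
            if self.alt_aa not in AA1:
                raise ProteinChangeError(f"missense alternate {self.alt_aa!r} not a standard amino acid")
            if self.alt_aa == self.ref_aa:
                raise ProteinChangeError("missense change cannot have alt == ref")
        if self.consequence == "silent" and self.alt_aa != self.ref_aa:
            raise ProteinChangeError("silent change must have alt == ref")

    @property
    def key(self) -> tuple[str, int, str]:
        """Protein-change identity: (ref, position, alt)."""
        return (self.ref_aa, self.position, self.alt_aa)

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class MutationCatalog:
    """Deduplicated missense catalog with per-key recurrence counts.

    ``records`` keeps every missense observation (first-occurrence order);
    ``recurrence`` counts observations per unique (ref, pos, alt) key.
    """

    records: list[MutationRecord] = field(default_factory=list)

    @property
    def unique_keys(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for rec in self.records:
            seen.setdefault(rec.key, None)
        return list(seen)

    @property
    def recurrence(self) -> dict[tuple[str, int, str], int]:
        return dict(Counter(rec.key for rec in self.records))

    def first_records(self) -> list[MutationRecord]:
        """One representative record per unique key, input order preserved."""
        seen: dict[tuple[str, int, str], MutationRecord] = {}
        for rec in self.records:
            seen.setdefault(rec.key, rec)
        return list(seen.values())

    def __len__(self) -> int:
        return len(self.unique_keys)


def _normalize_aa(token: str) -> str:
    """Map a 1- or 3-letter residue code (or stop) to the 1-letter alphabet."""
    if token in ("*", "X"):
        return "*"
    if len(token) == 1:
        code = token.upper()
        if code in AA1:
            return code
        raise ProteinChangeError(f"unknown residue code {token!r}")
    code = AA3_TO_1.get(token.upper())
    if code is None:
        raise ProteinChangeError(f"unknown residue code {token!r}")
    return code


def parse_protein_change(text: str) -> MutationRecord:
    """Parse an HGVS-like protein change into a :class:`MutationRecord`.

    Accepts 1-letter ("L95P") and 3-letter ("p.Leu95Pro") codes,
    stop gains ("p.R655*"), frameshifts ("p.K83fs", "p.K83Nfs*12")
    and silent notation ("L95L" or "p.L95=").

    >>> parse_protein_change("p.T27S").key
    ('T', 27, 'S')
    """
    token = text.strip()
    m = _CHANGE_RE.match(token)
    if m is None:
        raise ProteinChangeError(f"cannot parse protein change {text!r}")
    ref = _normalize_aa(m.group("ref"))
    if ref == "*":
        raise ProteinChangeError(f"reference residue cannot be a stop in {text!r}")
    position = int(m.group("pos"))
    if position < 1:
        raise ProteinChangeError(f"position must be >= 1 in {text!r}")

    rest = m.group("rest")
    fs_match = re.match(r"^(?P<alt>[A-Za-z]{1,3})?fs.*$", rest) if "fs" in rest else None
    if fs_match is not None:
        consequence = "frameshift"
        alt_token = fs_match.group("alt")
        alt = _normalize_aa(alt_token) if alt_token else ""
    else:
        if not rest:
            raise ProteinChangeError(f"missing alternate residue in {text!r}")
        alt = ref if rest == "=" else _normalize_aa(rest) if rest != "*" else "*"
        if alt == "*":
            consequence = "nonsense"
        elif alt == ref:
            consequence = "silent"
        else:
            consequence = "missense"
    return MutationRecord(
        raw_change=token, ref_aa=ref, position=position, alt_aa=alt, consequence=consequence
    )


def screen_missense(records: Iterable[MutationRecord]) -> MutationCatalog:
    """Keep missense records only, deduplicating at the protein-change level.

    Frameshift, nonsense (stop gain), silent and any other consequence
    classes are dropped; exclusion counts are logged. Re-screening a
    screened catalog's records is idempotent.
    """
    kept: list[MutationRecord] = []
    excluded = Counter()
    for rec in records:
        if rec.consequence == "missense":
            kept.append(rec)
        else:
            excluded[rec.consequence] += 1
    if excluded:
        logger.info("screen_missense excluded %s", dict(excluded))
    return MutationCatalog(records=kept)


def tabulate_by_cancer(catalog: MutationCatalog) -> pd.DataFrame:
    """Per-cancer-type summary: unique mutation count and occurrence count.

    Records lacking a cancer type are grouped under "unspecified".
    """
    rows = []
    for rec in catalog.records:
        ct = rec.cancer_type.strip() if rec.cancer_type else ""
        if not ct:
            logger.warning("record %s has no cancer_type; grouped as 'unspecified'", rec.label)
            ct = "unspecified"
        rows.append({"cancer_type": ct, "key": rec.label})
    if not rows:
        return pd.DataFrame(columns=["cancer_type", "unique_mutations", "occurrences"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("cancer_type", sort=False)
        .agg(unique_mutations=("key", "nunique"), occurrences=("key", "size"))
        .reset_index()
    )
    return out


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a tab-delimited mutation table.

    Requires a header with columns ``protein_change``, ``cancer_type``,
    ``source_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_change", "cancer_type", "source_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        base = parse_protein_change(row.protein_change)
        records.append(replace(base, cancer_type=row.cancer_type, source_id=row.source_id))
    return records


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write the screened catalog as TSV with consequence and recurrence columns."""
    recurrence = catalog.recurrence
    rows = [
        {
            "protein_change": rec.label,
            "cancer_type": rec.cancer_type,
            "source_id": rec.source_id,
            "consequence": rec.consequence,
            "recurrence": recurrence[rec.key],
        }
        for rec in catalog.records
    ]
    pd.DataFrame(
        rows, columns=["protein_change", "cancer_type", "source_id", "consequence", "recurrence"]
    ).to_csv(path, sep="\t", index=False)
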