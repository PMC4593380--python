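"""Impact classification: feature bundles and the four-tier rule engine.

Structure-level evidence alone does not rank a substitution; the verdict
comes from an ordered rule set codifying how practitioners weigh the
evidence — residue position (disordered loops are unjudgeable), the
stereochemical oddity of proline and glycine, charge networks and their
hydrogen-bond fallbacks, surface interface candidacy, and side-chain
bulk in hydrophobic cores. Rules fire in order; the first match decides:

R1  disordered region                                  -> unpredictable
R2  proline or glycine on either side                  -> drastic
R3  salt-bridge-engaged charge lost or inverted        -> drastic
R4  polar engagement kept (charge-complementary gain   -> very moderate;
    hydrogen-bond capability merely preserved          -> moderate)
R5  exposed interface candidate with disruptive change -> moderate
R6  hydrophobic core, bulkier nonpolar side chain      -> moderate
R7  anything else                                      -> very moderate

Classification is a pure function of :class:`SiteFeatures`; the rule
thresholds and residue tables ship in ``data/classify.yaml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml

from mxamut.catalog import MutationCatalog, MutationRecord
from mxamut.domains import DISORDERED_DOMAINS, DomainMap, assign_domain, load_domain_map

AA3_FROM_1 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1_FROM_3 = {v: k for k, v in AA3_FROM_1.items()}

_CHARGE = {**{aa: 1 for aa in "KRH"}, **{aa: -1 for aa in "DE"}}


class FeatureError(ValueError):
    """Raised when features cannot be derived or are incomplete."""


def load_classify_config(path: str | Path | None = None) -> dict:
    if path is None:
        with resources.files("mxamut.data").joinpath("classify.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    polarity = {}
    for category, aas in raw["polarity"].items():
        for aa in aas:
            polarity[aa] = category
    raw["polarity_by_aa"] = polarity
    return raw


class InteractionSummary(NamedTuple):
    """One contact of the wild-type residue: kind, partner, chain scope."""

    kind: str  # hydrogen_bond | salt_bridge | hydrophobic
    partner_aa: str  # 1-letter
    partner_position: int
    scope: str  # intra | inter

    def encode(self) -> str:
        return f"{self.kind}:{self.partner_aa}{self.partner_position}:{self.scope}"

    @classmethod
    def decode(cls, token: str) -> "InteractionSummary":
        kind, partner, scope = token.split(":")
        return cls(kind, partner[0], int(partner[1:]), scope)


@dataclass(frozen=True)
class SiteFeatures:
    """Per-mutation evidence bundle feeding the classifier."""

    mutation: str  # e.g. "E632K"
    ref_aa: str
    position: int
    alt_aa: str
    domain: str
    disordered: bool
    burial: str  # buried | exposed | unresolved
    polarity_before: str
    polarity_after: str
    interactions: tuple[InteractionSummary, ...]
    interface_candidate: bool
    volume_change: float  # alt minus ref side-chain volume, A^3
    provenance: str = "computed"  # computed | fixture

    def __post_init__(self) -> None:
        if self.disordered and self.interactions:
            raise FeatureError(f"{self.mutation}: disordered site cannot carry interactions")


@dataclass(frozen=True)
class ImpactEntry:
    mutation: str
    category: str  # drastic | moderate | very_moderate | unpredictable
    rule_id: str
    rationale: str


@dataclass
class ImpactReport:
    entries: list[ImpactEntry]

    def categories(self) -> dict[str, str]:
        return {e.mutation: e.category for e in self.entries}

    def counts(self) -> dict[str, int]:
        out = {"drastic": 0, "moderate": 0, "very_moderate": 0, "unpredictable": 0}
        for e in self.entries:
            out[e.category] = out.get(e.category, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Feature derivation


def derive_features(
    record: MutationRecord,
    domain_map: DomainMap | None = None,
    annotation: dict | None = None,
    structures: dict | None = None,
    config: dict | None = None,
) -> SiteFeatures:
    """Assemble the feature bundle for one missense mutation.

    Structural fields come either from an ``annotation`` row (a
    transcribed fixture, see :func:`load_feature_fixture`) or are
    computed on a routed reference structure in ``structures``
    ({structure_id: (StructureModel, chain)}). With neither available
    the features are incomplete and classification is refused.
    """
    if record.consequence != "missense":
        raise FeatureError(f"{record.raw_change}: only missense mutations are classifiable")
    cfg = config or load_classify_config()
    domain_map = domain_map or load_domain_map()
    domain = assign_domain(record.position, domain_map)
    disordered = domain in DISORDERED_DOMAINS
    polarity = cfg["polarity_by_aa"]
    volumes = cfg["volumes"]
    iface_sites = set(cfg.get("interface_candidate_sites", ()))

    if annotation is not None:
        burial = annotation["burial"]
        inter = tuple(
            InteractionSummary.decode(tok)
            for tok in str(annotation.get("interactions", "") or "").split(";")
            if tok
        )
        iface = bool(int(annotation.get("interface_candidate", 0)))
        provenance = "fixture"
    elif structures is not None:
        from mxamut.structure import classify_burial, detect_interactions, select_reference

        ref_id = select_reference(record.position)
        if ref_id == "none":
            burial, inter, iface = "exposed", (), record.position in iface_sites
        else:
            if ref_id not in structures:
                raise FeatureError(
                    f"{record.label}: reference structure {ref_id} not supplied"
                )
            model, chain = structures[ref_id]
            burial = classify_burial(model, chain, record.position).status
            inter = tuple(
                InteractionSummary(
                    kind=i.kind,
                    partner_aa=AA1_FROM_3.get(i.res_b[2], "X"),
                    partner_position=i.res_b[1],
                    scope="inter" if i.scope == "inter_chain" else "intra",
                )
                for i in detect_interactions(model, chain, record.position)
            )
            iface = record.position in iface_sites
        provenance = "computed"
    else:
        raise FeatureError(
            f"{record.label}: no structure and no fixture annotation; features incomplete"
        )
    if disordered:
        inter = ()
    return SiteFeatures(
        mutation=record.label,
        ref_aa=record.ref_aa,
        position=record.position,
        alt_aa=record.alt_aa,
        domain=domain,
        disordered=disordered,
        burial=burial,
        polarity_before=polarity[record.ref_aa],
        polarity_after=polarity[record.alt_aa],
        interactions=inter,
        interface_candidate=iface,
        volume_change=volumes[record.alt_aa] - volumes[record.ref_aa],
        provenance=provenance,
    )


def load_feature_fixture(path: str | Path | None = None) -> dict[str, dict]:
    """Load the packaged per-mutation feature table (transcribed evidence)."""
    if path is None:
        path = resources.files("mxamut.data").joinpath("table3_features.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {row["mutation"]: dict(row) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Rule engine


def _partner_charges(features: SiteFeatures, kinds: tuple[str, ...]) -> list[int]:
    return [
        _CHARGE.get(i.partner_aa, 0)
        for i in features.interactions
        if i.kind in kinds and i.partner_aa in _CHARGE
    ]


def classify_impact(features: SiteFeatures, config: dict | None = None) -> ImpactEntry:
    """Apply the ordered rule set; the first matching rule decides.

    Pure function of the feature bundle: same features, same verdict.
    """
    cfg = config or load_classify_config()
    hbond_capable = set(cfg["hbond_capable"])
    bulky = set(cfg["bulky_hydrophobes"])
    vol_thresh = float(cfg["volume_gain_threshold"])
    ref, alt = features.ref_aa, features.alt_aa
    before, after = features.polarity_before, features.polarity_after

    # R1: disordered loops carry no observable structure to judge against
    if features.disordered:
        return ImpactEntry(
            features.mutation, "unpredictable", "R1",
            f"{features.domain} is intrinsically disordered; structural outcome unobservable",
        )

    # R2: proline/glycine rewires backbone dihedral freedom either way
    if ref in "PG" or alt in "PG":
        which = ref if ref in "PG" else alt
        return ImpactEntry(
            features.mutation, "drastic", "R2",
            f"special residue {which} gained or lost; backbone trajectory/flexibility disrupted",
        )

    # R3: engaged charge lost outright, or inverted toward its partner's sign
    salt_partners = _partner_charges(features, ("salt_bridge",))
    if before in ("positive", "negative") and salt_partners:
        if alt not in hbond_capable:
            return ImpactEntry(
                features.mutation, "drastic", "R3",
                f"charged {ref} in salt bridge/charge network replaced by {alt} "
                "with no hydrogen-bond capability",
            )
        alt_charge = _CHARGE.get(alt, 0)
        if alt_charge != 0 and any(alt_charge == pc for pc in salt_partners):
            return ImpactEntry(
                features.mutation, "drastic", "R3",
                f"charge inversion: {alt} now carries the same sign as its salt-bridge partner",
            )

    # R4: polar engagement (H-bond or salt bridge) survives the substitution
    polar_partners = _partner_charges(features, ("hydrogen_bond", "salt_bridge"))
    polar_engaged = any(i.kind in ("hydrogen_bond", "salt_bridge") for i in features.interactions)
    if polar_engaged:
        alt_charge = _CHARGE.get(alt, 0)
        if alt_charge != 0 and any(alt_charge == -pc for pc in polar_partners):
            return ImpactEntry(
                features.mutation, "very_moderate", "R4",
                f"{alt} gains charge complementarity with its polar partner; "
                "interaction preserved or strengthened",
            )
        if alt in hbond_capable:
            return ImpactEntry(
                features.mutation, "moderate", "R4",
                f"{alt} retains hydrogen-bond capability toward the original polar partner(s)",
            )

    # R5: free surface residue at a candidate protein-partner interface
    if (
        features.burial == "exposed"
        and not features.interactions
        and features.interface_candidate
    ):
        polarity_loss = before in ("positive", "negative", "polar") and after in (
            "nonpolar",
            "weak_polar",
        )
        if polarity_loss or alt in bulky or alt == "C":
            return ImpactEntry(
                features.mutation, "moderate", "R5",
                "surface interface candidate: strong-polarity loss, bulky hydrophobe "
                "or modification-prone cysteine may perturb partner binding",
            )

    # R6: bulkier nonpolar side chain squeezed into a hydrophobic core
    if (
        any(i.kind == "hydrophobic" for i in features.interactions)
        and before == "nonpolar"
        and after == "nonpolar"
        and features.volume_change > vol_thresh
    ):
        return ImpactEntry(
            features.mutation, "moderate", "R6",
            f"hydrophobic core gains {features.volume_change:+.1f} A^3 of side-chain volume",
        )

    # R7: total fallback
    return ImpactEntry(
        features.mutation, "very_moderate", "R7",
        "no engaged interaction disrupted and no disruptive stereochemical change",
    )


# ---------------------------------------------------------------------------
# Report assembly


def annotate_catalog(
    catalog: MutationCatalog,
    annotations: dict[str, dict] | None = None,
    structures: dict | None = None,
    conservation: dict[int, str] | None = None,
    domain_map: DomainMap | None = None,
    config: dict | None = None,
) -> pd.DataFrame:
    """Full per-mutation report table for a screened catalog."""
    cfg = config or load_classify_config()
    domain_map = domain_map or load_domain_map()
    cancer_types: dict[str, list[str]] = {}
    for rec in catalog.records:
        cancer_types.setdefault(rec.label, [])
        if rec.cancer_type and rec.cancer_type not in cancer_types[rec.label]:
            cancer_types[rec.label].append(rec.cancer_type)
    rows = []
    for rec in catalog.first_records():
        ann = annotations.get(rec.label) if annotations else None
        feats = derive_features(rec, domain_map, ann, structures, cfg)
        entry = classify_impact(feats, cfg)
        rows.append(
            {
                "mutation": rec.label,
                "cancer_types": "; ".join(cancer_types[rec.label]),
                "domain": feats.domain,
                "conservation": conservation.get(rec.position, "") if conservation else "",
                "burial": feats.burial,
                "polarity_before": feats.polarity_before,
                "polarity_after": feats.polarity_after,
                "interactions": ";".join(i.encode() for i in feats.interactions),
                "impact": entry.category,
                "rule": entry.rule_id,
                "rationale": entry.rationale,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mutation", "cancer_types", "domain", "conservation", "burial",
            "polarity_before", "polarity_after", "interactions", "impact",
            "rule", "rationale",
        ],
    )


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation report as TSV (default) or JSON (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    else:
        report.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
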