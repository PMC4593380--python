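"""Structural evidence extraction from PDB crystal structures.

Everything here operates on plain distance geometry, matching how the
source structures were originally analyzed:

* residue-residue interactions are called from heavy-atom center
  distances alone — 2.7-3.5 Å for hydrogen bonds, ≤4 Å for salt bridges
  and hydrophobic contacts (no angle terms);
* burial is called from Shrake-Rupley solvent-accessible surface area
  relative to per-residue-type theoretical maxima;
* mutant-versus-wild-type comparison uses least-squares (Kabsch)
  superposition RMSD.

Inter-chain contacts are searched over the chains deposited in the file
(crystal-lattice oligomer copies); no symmetry mates are generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: numeric guard so planted boundary distances written at PDB precision
#: (3 decimals) compare as intended against the window edges
_EPS = 1e-9


def _load_config(path: str | Path | None = None) -> dict:
    if path is None:
        with resources.files("mxamut.data").joinpath("structure.yaml").open() as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(Path(path).read_text())


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance windows (Å) for the three interaction kinds."""

    hbond_min: float = 2.7
    hbond_max: float = 3.5
    contact_max: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.hbond_min < self.hbond_max):
            raise ValueError("require 0 < hbond_min < hbond_max")
        if self.contact_max <= 0:
            raise ValueError("contact_max must be positive")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.name}{self.number}{self.icode}".rstrip()


@dataclass
class StructureModel:
    """Polymer residues plus a separate ligand set (waters and H removed)."""

    structure_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for res in self.residues:
            if res.chain == chain and res.number == number and res.icode == icode:
                return res
        raise KeyError(f"residue {chain}:{number}{icode} not in model")

    def has_residue(self, chain: str, number: int, icode: str = "") -> bool:
        try:
            self.residue(chain, number, icode)
            return True
        except KeyError:
            return False

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def move(res: Residue) -> Residue:
            atoms = [
                Atom(a.name, a.element, tuple(R @ a.xyz + t), a.occupancy, a.altloc)
                for a in res.atoms
            ]
            return Residue(res.chain, res.number, res.icode, res.name, atoms)

        return StructureModel(
            self.structure_id,
            [move(r) for r in self.residues],
            [move(r) for r in self.ligands],
        )


@dataclass(frozen=True)
class Interaction:
    """A detected residue-residue contact. (A,B) and (B,A) are the same contact."""

    kind: str  # hydrogen_bond | salt_bridge | hydrophobic
    res_a: tuple[str, int, str]  # (chain, number, 3-letter name)
    res_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance: float
    scope: str  # intra_chain | inter_chain

    def canonical(self) -> tuple:
        """Order-independent identity for symmetry comparisons."""
        a = (self.res_a, self.atom_a)
        b = (self.res_b, self.atom_b)
        lo, hi = sorted([a, b])
        return (self.kind, lo, hi, round(self.distance, 3))


@dataclass(frozen=True)
class BurialAssessment:
    residue: tuple[str, int, str]
    sidechain_sasa: float
    total_sasa: float
    relative_sasa: float
    status: str  # buried | exposed | unresolved


# ---------------------------------------------------------------------------
# PDB reading


def _resolve_altlocs(groups: Mapping[str, list[Atom]]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties alphabetical."""
    kept = []
    for name, alts in groups.items():
        best = min(alts, key=lambda a: (-a.occupancy, a.altloc))
        kept.append(best)
    return kept


def read_structure(path: str | Path, structure_id: str | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Waters and hydrogens are dropped; alternate locations are resolved to
    the highest-occupancy conformer (ties broken alphabetically by altloc
    id); HETATM ligands (nucleotide analogues, metal ions, ...) are kept
    in a separate ligand list.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"{path}: no ATOM records found")
    model = StructureModel(structure_id=structure_id or (st.name or Path(path).stem))
    for chain in st[0]:
        for res in chain:
            groups: dict[str, list[Atom]] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                groups.setdefault(at.name, []).append(
                    Atom(
                        name=at.name,
                        element=at.element.name.upper(),
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        altloc=at.altloc or "",
                    )
                )
            atoms = _resolve_altlocs(groups)
            if not atoms:
                continue
            atoms.sort(key=lambda a: a.name)
            out = Residue(
                chain=chain.name,
                number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=res.name,
                atoms=atoms,
            )
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if res.het_flag == "H" and not is_aa:
                model.ligands.append(out)
            else:
                model.residues.append(out)
    if not model.residues and not model.ligands:
        raise ValueError(f"{path}: no atoms after filtering")
    return model


# ---------------------------------------------------------------------------
# Atom typing


class AtomTyping:
    """Typing tables: charged-group atoms, donors/acceptors, hydrophobic carbons."""

    def __init__(self, config: dict | None = None):
        cfg = config or _load_config()
        self.positive = {k: set(v) for k, v in cfg["positive_atoms"].items()}
        self.negative = {k: set(v) for k, v in cfg["negative_atoms"].items()}
        self.hydrophobic = {k: set(v) for k, v in cfg["hydrophobic_atoms"].items()}
        if cfg.get("include_tyr_ring", True):
            self.hydrophobic["TYR"] = set(cfg["tyr_ring_atoms"])

    def charge(self, res_name: str, atom_name: str, *, is_terminal_n: bool = False) -> int:
        if atom_name == "OXT":
            return -1
        if is_terminal_n and atom_name == "N":
            return 1
        if atom_name in self.positive.get(res_name, ()):
            return 1
        if atom_name in self.negative.get(res_name, ()):
            return -1
        return 0

    def is_donor_acceptor(self, element: str) -> bool:
        # side-chain N/O plus backbone carbonyl O and amide N, i.e. every
        # heavy N or O in a standard residue
        return element in ("N", "O")

    def is_hydrophobic(self, res_name: str, atom_name: str) -> bool:
        return atom_name in self.hydrophobic.get(res_name, ())


# ---------------------------------------------------------------------------
# Interaction detection


def _atom_arrays(model: StructureModel, typing: AtomTyping):
    """Flatten polymer atoms to parallel arrays for neighbor search."""
    first_by_chain: dict[str, int] = {}
    for res in model.residues:
        if res.chain not in first_by_chain or res.number < first_by_chain[res.chain]:
            first_by_chain[res.chain] = res.number
    coords, meta = [], []
    for ri, res in enumerate(model.residues):
        is_nterm = res.number == first_by_chain[res.chain]
        for at in res.atoms:
            coords.append(at.coord)
            meta.append(
                (
                    ri,
                    at.name,
                    typing.charge(res.name, at.name, is_terminal_n=is_nterm),
                    typing.is_donor_acceptor(at.element),
                    typing.is_hydrophobic(res.name, at.name),
                )
            )
    return np.asarray(coords, dtype=float), meta


def _classify_pair(
    d: float,
    charge_a: int,
    charge_b: int,
    dono_a: bool,
    dono_b: bool,
    hyd_a: bool,
    hyd_b: bool,
    criteria: InteractionCriteria,
) -> str | None:
    """Per-atom-pair kind with priority salt_bridge > hydrogen_bond > hydrophobic."""
    if charge_a * charge_b < 0 and d <= criteria.contact_max + _EPS:
        return "salt_bridge"
    if dono_a and dono_b and (criteria.hbond_min - _EPS) <= d <= (criteria.hbond_max + _EPS):
        return "hydrogen_bond"
    if hyd_a and hyd_b and d <= criteria.contact_max + _EPS:
        return "hydrophobic"
    return None


def detect_interactions(
    model: StructureModel,
    chain: str,
    number: int,
    criteria: InteractionCriteria | None = None,
    typing: AtomTyping | None = None,
    icode: str = "",
) -> list[Interaction]:
    """All distance-rule contacts of one residue against the rest of the model.

    Sequence-adjacent residues (|Δposition| ≤ 1 on the same chain) are
    excluded; partners on a different chain are flagged ``inter_chain``.
    Glycine (no side-chain heavy atoms) is evaluated on its backbone only,
    with a warning.
    """
    criteria = criteria or InteractionCriteria()
    typing = typing or AtomTyping()
    target = model.residue(chain, number, icode)
    if not any(a.name not in BACKBONE_ATOMS for a in target.atoms):
        logger.warning("residue %s has no side-chain heavy atoms; backbone-only", target.label)
    coords, meta = _atom_arrays(model, typing)
    res_list = model.residues
    target_idx = next(
        i for i, r in enumerate(res_list) if r.id == target.id
    )
    tree = cKDTree(coords)
    out: list[Interaction] = []
    seen: set[tuple] = set()
    for at in target.atoms:
        q = at.xyz
        a_charge = typing.charge(
            target.name,
            at.name,
            is_terminal_n=target.number == min(r.number for r in res_list if r.chain == chain),
        )
        a_dono = typing.is_donor_acceptor(at.element)
        a_hyd = typing.is_hydrophobic(target.name, at.name)
        for j in tree.query_ball_point(q, criteria.contact_max + 1e-6):
            ri, b_name, b_charge, b_dono, b_hyd = meta[j]
            partner = res_list[ri]
            if ri == target_idx:
                continue
            if partner.chain == chain and abs(partner.number - number) <= 1:
                continue
            d = float(np.linalg.norm(q - coords[j]))
            kind = _classify_pair(d, a_charge, b_charge, a_dono, b_dono, a_hyd, b_hyd, criteria)
            if kind is None:
                continue
            inter = Interaction(
                kind=kind,
                res_a=(target.chain, target.number, target.name),
                res_b=(partner.chain, partner.number, partner.name),
                atom_a=at.name,
                atom_b=b_name,
                distance=d,
                scope="inter_chain" if partner.chain != chain else "intra_chain",
            )
            key = inter.canonical()
            if key not in seen:
                seen.add(key)
                out.append(inter)
    out.sort(key=lambda i: (i.res_b[0], i.res_b[1], i.atom_a, i.atom_b))
    return out


def residue_environment(
    model: StructureModel,
    chain: str,
    number: int,
    criteria: InteractionCriteria | None = None,
    typing: AtomTyping | None = None,
) -> dict[tuple[str, int, str], list[Interaction]]:
    """Interactions of one residue grouped by partner residue."""
    env: dict[tuple[str, int, str], list[Interaction]] = {}
    for inter in detect_interactions(model, chain, number, criteria, typing):
        env.setdefault(inter.res_b, []).append(inter)
    return env


# ---------------------------------------------------------------------------
# Solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    config: dict | None = None,
    include_ligands: bool = True,
) -> dict:
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``{"atom": per-atom Å² array, "residue": {(chain, num, icode):
    {"total", "sidechain"}}}``. Deterministic for a fixed point count.
    Unknown elements fall back to the default radius with a warning.
    """
    cfg = config or _load_config()
    radii_table = cfg["vdw_radii"]
    default_r = cfg["default_radius"]

    residues = list(model.residues) + (list(model.ligands) if include_ligands else [])
    atoms: list[tuple[Residue, Atom]] = [(res, at) for res in residues for at in res.atoms]
    if not atoms:
        raise ValueError("model has no atoms")
    coords = np.array([at.xyz for _, at in atoms])
    radii = np.empty(len(atoms))
    for i, (_, at) in enumerate(atoms):
        r = radii_table.get(at.element)
        if r is None:
            logger.warning("unknown element %r; default radius %.2f", at.element, default_r)
            r = default_r
        radii[i] = r
    ext = radii + probe

    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(atoms))
    max_ext = ext.max()
    for i in range(len(atoms)):
        pts = coords[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points

    per_res: dict[tuple[str, int, str], dict[str, float]] = {}
    for (res, at), area in zip(atoms, areas):
        entry = per_res.setdefault(res.id, {"total": 0.0, "sidechain": 0.0})
        entry["total"] += area
        if at.name not in BACKBONE_ATOMS:
            entry["sidechain"] += area
    return {"atom": areas, "residue": per_res}


def classify_burial(
    model: StructureModel,
    chain: str,
    number: int,
    threshold: float | None = None,
    sasa_result: dict | None = None,
    config: dict | None = None,
) -> BurialAssessment:
    """Call a residue buried or exposed from its relative SASA.

    Relative SASA is the residue's total area over its residue-type
    theoretical maximum; buried iff below the threshold (default 0.25).
    Residues absent from the structure return status "unresolved".
    """
    cfg = config or _load_config()
    if threshold is None:
        threshold = cfg["burial"]["relative_sasa_threshold"]
    if not model.has_residue(chain, number):
        return BurialAssessment((chain, number, "?"), float("nan"), float("nan"), float("nan"), "unresolved")
    res = model.residue(chain, number)
    result = sasa_result or sasa(model, config=cfg)
    entry = result["residue"][res.id]
    ref = cfg["burial"]["reference_areas"].get(res.name)
    if ref is None:
        logger.warning("no reference area for %s; treating as exposed", res.name)
        rel = 1.0
    else:
        rel = entry["total"] / ref
    status = "buried" if rel < threshold else "exposed"
    return BurialAssessment(
        residue=(chain, number, res.name),
        sidechain_sasa=entry["sidechain"],
        total_sasa=entry["total"],
        relative_sasa=rel,
        status=status,
    )


# ---------------------------------------------------------------------------
# Reference routing


@dataclass(frozen=True)
class ReferenceRoute:
    """Which deposited structure serves as reference for each region.

    Switch I is a mobile loop ordered only with a bound GTP analogue, so
    its positions route to the nucleotide-bound structure; disordered
    regions route to "none".
    """

    switch_i_positions: frozenset = frozenset({95, 96})
    switch_i_structure: str = "4P4S"
    domain_structures: tuple = (
        ("G domain", "4P4U"),
        ("Stalk", "3LJB"),
        ("BSE", "3SZR"),
        ("Hinge 1", "3SZR"),
    )

    @classmethod
    def from_config(cls, config: dict | None = None) -> "ReferenceRoute":
        cfg = (config or _load_config())["reference_route"]
        return cls(
            switch_i_positions=frozenset(cfg["switch_i_positions"]),
            switch_i_structure=cfg["switch_i_structure"],
            domain_structures=tuple(cfg["domain_structures"].items()),
        )


def select_reference(position: int, route: ReferenceRoute | None = None, domain_map=None) -> str:
    """Map a residue position to its reference structure id, or "none".

    Disordered regions (N'-loop, L4) have no crystal coverage and route
    to "none".
    """
    from mxamut.domains import DISORDERED_DOMAINS, assign_domain, load_domain_map

    route = route or ReferenceRoute.from_config()
    domain_map = domain_map or load_domain_map()
    if position in route.switch_i_positions:
        return route.switch_i_structure
    domain = assign_domain(position, domain_map)
    if domain in DISORDERED_DOMAINS:
        return "none"
    return dict(route.domain_structures).get(domain, "none")


# ---------------------------------------------------------------------------
# Superposition


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` with ``R @ b + t`` the
    fitted position of each B atom and a proper rotation (det +1).
    Requires ≥3 matched, non-collinear atoms.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3 with matched order")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate sets leave the rotation underdetermined
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    fitted = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - A) ** 2, axis=1))))
    return R, t, rmsd
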