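"""Synthetic fixtures with planted, analytically known structure.

Every input family the pipeline consumes can be generated here with
known ground truth: minimal PDB files whose named atom pairs sit at
exact planted distances, alignments with exact per-column group
conservation, and mutation tables embedding the published 24-occurrence
catalog plus seeded decoys. Fixture PDB files use idealized side-chain
geometry — only the atoms needed for atom typing — which suffices
because every detection criterion is distance-based.

Each generator returns ``(text, ground_truth)``; regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from mxamut.conservation import DYNAMIN_SET, MX_SET, RESIDUE_GROUPS

#: minimal side-chain "probe" atom used for each residue type
PROBE_ATOMS = {
    "LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1",
    "SER": "OG", "THR": "OG1", "ASN": "OD1",
    "LEU": "CD1", "VAL": "CG1", "ILE": "CD1", "ALA": "CB", "MET": "CE",
}

_OCTAHEDRAL = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=float
)


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element, occ=1.0, altloc=" "):
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_f}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{element:>2s}"
    )


def _residue_lines(serial, resname, chain, resseq, probe_xyz, direction, backbone_radius=2.9):
    """Backbone placed radially behind the probe atom along ``direction``.

    ``backbone_radius`` sets how far the amide N sits behind the probe;
    scenes place target backbones at a larger radius so that no backbone
    N/O strays into a partner's interaction window.
    """
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    # any unit vector orthogonal to u, chosen deterministically
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(u, ref)
    perp /= np.linalg.norm(perp)
    probe_xyz = np.asarray(probe_xyz, float)
    r = backbone_radius
    atoms = [
        ("N", probe_xyz + u * r, "N"),
        ("CA", probe_xyz + u * (r - 1.4), "C"),
        ("C", probe_xyz + u * r + perp * 1.3, "C"),
        ("O", probe_xyz + u * r + perp * 2.5, "O"),
        (PROBE_ATOMS[resname], probe_xyz, PROBE_ATOMS[resname][0]),
    ]
    lines = []
    for i, (name, xyz, elem) in enumerate(atoms):
        lines.append(_pdb_atom(serial + i, name, resname, chain, resseq, xyz, elem))
    return lines, serial + len(atoms)


def _scene(target, partners, header_lines=()):
    """Build a PDB scene: target probe atom at the origin, each partner's
    probe atom at ``distance`` along its own octahedral direction."""
    if len(partners) > len(_OCTAHEDRAL):
        raise ValueError(f"at most {len(_OCTAHEDRAL)} partners supported")
    t_resname, t_chain, t_resseq = target
    lines = [f"REMARK 300 {h}" for h in header_lines]
    serial = 1
    u_target = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    res_lines, serial = _residue_lines(
        serial, t_resname, t_chain, t_resseq, (0, 0, 0), u_target, backbone_radius=6.0
    )
    lines += res_lines
    for (resname, chain, resseq, distance), direction in zip(partners, _OCTAHEDRAL):
        if distance < 1.0:
            raise ValueError(f"planted distance {distance} A violates covalent geometry")
        res_lines, serial = _residue_lines(
            serial, resname, chain, resseq, direction * distance, direction
        )
        lines += res_lines
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_interaction_fixture(kind: str, distance: float, seed: int = 0) -> tuple[str, dict]:
    """Two-residue (or residue + shell) PDB with one planted atom pair.

    Kinds: ``salt_bridge`` (Lys NZ - Asp OD1), ``hbond`` (Ser OG - Asn
    OD1), ``hydrophobic`` (Leu CD1 - Leu CD1), or ``hydrophobic_pocket``
    (Leu center with 6 planted Leu partners).
    """
    if distance < 1.0:
        raise ValueError(f"planted distance {distance} A violates covalent geometry")
    if kind == "salt_bridge":
        target, partners = ("LYS", "A", 10), [("ASP", "A", 20, distance)]
        pair = ("NZ", "OD1")
    elif kind == "hbond":
        target, partners = ("SER", "A", 10), [("ASN", "A", 20, distance)]
        pair = ("OG", "OD1")
    elif kind == "hydrophobic":
        target, partners = ("LEU", "A", 10), [("LEU", "A", 20, distance)]
        pair = ("CD1", "CD1")
    elif kind == "hydrophobic_pocket":
        if distance < 2.9:
            raise ValueError("pocket distance < 2.9 A would let partner shells touch")
        target = ("LEU", "A", 50)
        partners = [("LEU", "A", 10 + 3 * i, distance) for i in range(6)]
        pair = ("CD1", "CD1")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    text = _scene(
        target,
        partners,
        header_lines=[f"SYNTHETIC {kind} FIXTURE seed={seed} distance={distance:.3f}"],
    )
    truth = {
        "kind": kind,
        "seed": seed,
        "planted_distance": distance,
        "target": {"chain": target[1], "number": target[2], "name": target[0]},
        "partners": [
            {"chain": c, "number": n, "name": r, "distance": d} for r, c, n, d in partners
        ],
        "atom_pair": pair,
    }
    return text, truth


def make_dimer_fixture(distance: float, seed: int = 0, single_chain: bool = False) -> tuple[str, dict]:
    """Charged pair across chains A and B (Arg NH1 - Glu OE1) at a planted
    distance; with ``single_chain`` both residues sit on chain A."""
    if distance < 1.0:
        raise ValueError(f"planted distance {distance} A violates covalent geometry")
    chain_b = "A" if single_chain else "B"
    target = ("ARG", "A", 10)
    partners = [("GLU", chain_b, 20, distance)]
    text = _scene(
        target,
        partners,
        header_lines=[f"SYNTHETIC dimer FIXTURE seed={seed} distance={distance:.3f}"],
    )
    truth = {
        "kind": "dimer_interface",
        "seed": seed,
        "planted_distance": distance,
        "expected_scope": "intra_chain" if single_chain else "inter_chain",
        "target": {"chain": "A", "number": 10, "name": "ARG"},
        "partner": {"chain": chain_b, "number": 20, "name": "GLU"},
        "atom_pair": ("NH1", "OE1"),
    }
    return text, truth


def make_burial_fixture(buried: bool = True, n_shell: int = 80, seed: int = 0) -> tuple[str, dict]:
    """Central compact Ala either fully enclosed by a carbon shell or isolated."""
    lines = [f"REMARK 300 SYNTHETIC burial FIXTURE seed={seed} buried={buried}"]
    serial = 1
    central = [
        ("N", (2.2, 1.2, 0.0), "N"),
        ("CA", (1.5, 0.0, 0.0), "C"),
        ("C", (2.2, -1.2, 0.0), "C"),
        ("O", (3.4, -1.2, 0.0), "O"),
        ("CB", (0.0, 0.0, 0.0), "C"),
    ]
    for name, xyz, elem in central:
        lines.append(_pdb_atom(serial, name, "ALA", "A", 50, np.asarray(xyz), elem))
        serial += 1
    if buried:
        i = np.arange(n_shell, dtype=float) + 0.5
        phi = np.arccos(1.0 - 2.0 * i / n_shell)
        theta = np.pi * (1.0 + 5.0**0.5) * i
        shell = 5.0 * np.column_stack(
            (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
        )
        # shell centered on the residue's geometric middle, not the probe
        center = np.array([1.7, 0.0, 0.0])
        for k, xyz in enumerate(shell + center):
            lines.append(_pdb_atom(serial, "CB", "ALA", "B", 100 + k, xyz, "C"))
            serial += 1
    lines.append("END")
    truth = {"kind": "burial", "seed": seed, "expected_status": "buried" if buried else "exposed"}
    return "\n".join(lines) + "\n", truth


def make_mxa_fact_scenes(seed: int = 0) -> dict[str, tuple[str, dict]]:
    """Synthetic stand-in scenes for the published MxA structure facts.

    These plant the discussed residue identities at interacting
    distances: the Hinge 1 E632-R640 salt bridge, the inter-molecular
    R654-D478 BSE-Stalk salt bridge, R522's three-glutamate charge
    network, and L95's six-residue hydrophobic pocket. They are
    synthetic stand-ins, not crystallographic coordinates.
    """
    scenes = {}
    scenes["hinge_salt_bridge"] = (
        _scene(("GLU", "A", 632), [("ARG", "A", 640, 3.0)],
               [f"SYNTHETIC MxA hinge scene seed={seed}"]),
        {"target": ("A", 632), "partner": (640, "salt_bridge", "intra_chain")},
    )
    scenes["bse_stalk_interface"] = (
        _scene(("ARG", "A", 654), [("ASP", "B", 478, 3.2)],
               [f"SYNTHETIC MxA BSE-Stalk scene seed={seed}"]),
        {"target": ("A", 654), "partner": (478, "salt_bridge", "inter_chain")},
    )
    scenes["stalk_charge_network"] = (
        _scene(
            ("ARG", "A", 522),
            [("GLU", "A", 466, 3.1), ("GLU", "A", 467, 3.3), ("GLU", "A", 518, 3.6)],
            [f"SYNTHETIC MxA stalk network scene seed={seed}"],
        ),
        {"target": ("A", 522), "partners": {466: "salt_bridge", 467: "salt_bridge", 518: "salt_bridge"}},
    )
    pocket_partners = [
        ("LEU", "A", 87, 3.8), ("VAL", "A", 93, 3.9), ("LEU", "A", 107, 3.7),
        ("LEU", "A", 109, 3.8), ("ILE", "A", 143, 3.9), ("LEU", "A", 164, 3.6),
    ]
    scenes["g_domain_pocket"] = (
        _scene(("LEU", "A", 95), pocket_partners, [f"SYNTHETIC MxA L95 pocket scene seed={seed}"]),
        {"target": ("A", 95), "partners": {n: "hydrophobic" for _, _, n, _ in pocket_partners}},
    )
    return scenes


# ---------------------------------------------------------------------------
# Alignment fixtures


def make_msa(
    column_specs: list[tuple[float, float]],
    seed: int = 0,
    mx_set: tuple[str, ...] = MX_SET,
    dynamin_set: tuple[str, ...] = DYNAMIN_SET,
    reference_id: str = "hsMxA",
) -> tuple[str, dict]:
    """Aligned FASTA whose per-column group conservation is exact.

    ``column_specs`` gives (mx_fraction, dynamin_fraction) per column;
    each fraction must be a multiple of 1/len(subset) (and the Mx
    fraction at least 1/len(mx_set): the reference sequence belongs to
    the Mx subset and always matches itself).
    """
    rng = np.random.default_rng(seed)
    if reference_id not in mx_set:
        raise ValueError("reference must belong to the Mx subset")
    ids = list(mx_set) + list(dynamin_set)
    groups: dict[str, list[str]] = {}
    for aa, g in RESIDUE_GROUPS.items():
        groups.setdefault(g, []).append(aa)
    group_names = sorted(groups)
    cols = {sid: [] for sid in ids}
    truth_cols = []
    for ci, (mx_frac, dyn_frac) in enumerate(column_specs):
        k_mx = mx_frac * len(mx_set)
        k_dyn = dyn_frac * len(dynamin_set)
        for k, frac, name in ((k_mx, mx_frac, "mx"), (k_dyn, dyn_frac, "dynamin")):
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"column {ci}: {name} fraction {frac} unreachable with subset size")
        k_mx, k_dyn = round(k_mx), round(k_dyn)
        if k_mx < 1:
            raise ValueError(f"column {ci}: mx fraction must cover the reference sequence")
        ref_group = group_names[rng.integers(len(group_names))]
        other_groups = [g for g in group_names if g != ref_group]

        def sample_match():
            return groups[ref_group][rng.integers(len(groups[ref_group]))]

        def sample_mismatch():
            g = other_groups[rng.integers(len(other_groups))]
            return groups[g][rng.integers(len(groups[g]))]

        # deterministic placement: reference matches first, then remaining
        # subset members in a seeded order
        mx_members = [reference_id] + [s for s in mx_set if s != reference_id]
        mx_order = [mx_members[0]] + list(rng.permutation(mx_members[1:]))
        dyn_order = list(rng.permutation(list(dynamin_set)))
        assign = {}
        for i, sid in enumerate(mx_order):
            assign[sid] = sample_match() if i < k_mx else sample_mismatch()
        for i, sid in enumerate(dyn_order):
            assign[sid] = sample_match() if i < k_dyn else sample_mismatch()
        for sid in ids:
            cols[sid].append(assign[sid])
        truth_cols.append({"mx_fraction": mx_frac, "dynamin_fraction": dyn_frac, "ref_group": ref_group})
    out = []
    for sid in ids:
        out.append(f">{sid}")
        out.append("".join(cols[sid]))
    truth = {"kind": "msa", "seed": seed, "reference_id": reference_id, "columns": truth_cols}
    return "\n".join(out) + "\n", truth


# ---------------------------------------------------------------------------
# Mutation-table fixtures


_DECOY_CANCERS = ("decoy carcinoma", "decoy lymphoma", "decoy sarcoma")


def make_mutation_table(n_decoys: int = 0, seed: int = 0, protein_length: int = 662) -> tuple[str, dict]:
    """The packaged published-catalog transcription plus seeded decoy rows.

    Decoys span all consequence classes. The ground-truth sidecar
    records, per generated row, its consequence and unique key, plus the
    expected unique-missense count after screening.
    """
    rng = np.random.default_rng(seed)
    base = resources.files("mxamut.data").joinpath("table1.tsv").read_text()
    lines = base.strip().split("\n")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    truth_rows = []
    keys = set()
    for line in lines[1:]:
        change = line.split("\t")[0].removeprefix("p.")
        ref, pos, alt = change[0], int(change[1:-1]), change[-1]
        keys.add((ref, pos, alt))
        truth_rows.append({"change": change, "consequence": "missense"})
    for i in range(n_decoys):
        pos = int(rng.integers(1, protein_length + 1))
        ref = aas[rng.integers(len(aas))]
        kind = ("missense", "silent", "nonsense", "frameshift")[rng.integers(4)]
        if kind == "missense":
            alt = aas[rng.integers(len(aas))]
            while alt == ref:
                alt = aas[rng.integers(len(aas))]
            change = f"p.{ref}{pos}{alt}"
            keys.add((ref, pos, alt))
        elif kind == "silent":
            change = f"p.{ref}{pos}{ref}"
        elif kind == "nonsense":
            change = f"p.{ref}{pos}*"
        else:
            change = f"p.{ref}{pos}fs"
        cancer = _DECOY_CANCERS[rng.integers(len(_DECOY_CANCERS))]
        lines.append(f"{change}\t{cancer}\tDECOY-{i}")
        truth_rows.append({"change": change.removeprefix("p."), "consequence": kind})
    truth = {
        "kind": "mutation_table",
        "seed": seed,
        "n_decoys": n_decoys,
        "rows": truth_rows,
        "expected_unique_missense": len(keys),
    }
    return "\n".join(lines) + "\n", truth


def write_fixture(kind: str, out_dir: str | Path, seed: int = 0, **kwargs) -> Path:
    """Generate a fixture by kind and write it with its JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind in ("salt_bridge", "hbond", "hydrophobic", "hydrophobic_pocket"):
        text, truth = make_interaction_fixture(kind, kwargs.pop("distance", 3.0), seed)
        name = f"{kind}.pdb"
    elif kind == "dimer_interface":
        text, truth = make_dimer_fixture(kwargs.pop("distance", 3.2), seed, **kwargs)
        name = "dimer.pdb"
    elif kind == "msa":
        text, truth = make_msa(kwargs.pop("column_specs", [(1.0, 1.0), (1.0, 0.0)]), seed)
        name = "alignment.fasta"
    elif kind == "mutation_table":
        text, truth = make_mutation_table(kwargs.pop("n_decoys", 10), seed)
        name = "mutations.tsv"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    path = out_dir / name
    path.write_text(text)
    path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(truth, indent=2))
    return path
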