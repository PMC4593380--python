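"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: the interaction
oracle is a plain nested-loop scan with its own hard-coded typing
tables, and the superposition oracle is Horn's quaternion
eigenvector method rather than SVD.
"""

import math

import numpy as np

POSITIVE = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}
HYDROPHOBIC = {
    ("ALA", "CB"),
    ("VAL", "CB"), ("VAL", "CG1"), ("VAL", "CG2"),
    ("LEU", "CB"), ("LEU", "CG"), ("LEU", "CD1"), ("LEU", "CD2"),
    ("ILE", "CB"), ("ILE", "CG1"), ("ILE", "CG2"), ("ILE", "CD1"),
    ("MET", "CB"), ("MET", "CG"), ("MET", "CE"),
    ("PHE", "CB"), ("PHE", "CG"), ("PHE", "CD1"), ("PHE", "CD2"),
    ("PHE", "CE1"), ("PHE", "CE2"), ("PHE", "CZ"),
    ("TRP", "CB"), ("TRP", "CG"), ("TRP", "CD1"), ("TRP", "CD2"),
    ("TRP", "CE2"), ("TRP", "CE3"), ("TRP", "CZ2"), ("TRP", "CZ3"), ("TRP", "CH2"),
    ("PRO", "CB"), ("PRO", "CG"), ("PRO", "CD"),
    ("CYS", "CB"),
    ("TYR", "CG"), ("TYR", "CD1"), ("TYR", "CD2"),
    ("TYR", "CE1"), ("TYR", "CE2"), ("TYR", "CZ"),
}

EPS = 1e-9


def brute_force_interactions(model, chain, number):
    """All-pair distance scan for one residue; returns canonical tuples.

    Termini handling mirrors the detector's contract: first residue per
    chain has a positive amide N; OXT is negative.
    """
    first = {}
    for res in model.residues:
        first.setdefault(res.chain, res.number)
        first[res.chain] = min(first[res.chain], res.number)

    def charge(res, atom):
        if atom.name == "OXT":
            return -1
        if atom.name == "N" and res.number == first[res.chain]:
            return 1
        if (res.name, atom.name) in POSITIVE:
            return 1
        if (res.name, atom.name) in NEGATIVE:
            return -1
        return 0

    target = next(r for r in model.residues if r.chain == chain and r.number == number)
    found = set()
    for partner in model.residues:
        if partner is target:
            continue
        if partner.chain == chain and abs(partner.number - number) <= 1:
            continue
        for a in target.atoms:
            for b in partner.atoms:
                d = math.dist(a.coord, b.coord)
                if d > 4.0 + EPS:
                    continue
                ca, cb = charge(target, a), charge(partner, b)
                if ca * cb < 0:
                    kind = "salt_bridge"
                elif (
                    a.element in "NO"
                    and b.element in "NO"
                    and 2.7 - EPS <= d <= 3.5 + EPS
                ):
                    kind = "hydrogen_bond"
                elif (target.name, a.name) in HYDROPHOBIC and (partner.name, b.name) in HYDROPHOBIC:
                    kind = "hydrophobic"
                else:
                    continue
                lo, hi = sorted(
                    [((target.chain, target.number, target.name), a.name),
                     ((partner.chain, partner.number, partner.name), b.name)]
                )
                found.add((kind, lo, hi, round(d, 3)))
    return found


def quaternion_superpose_rmsd(A, B):
    """Horn's closed-form quaternion fit of B onto A; returns RMSD."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    M = B0.T @ A0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    )
    fitted = B0 @ R.T
    return float(np.sqrt(np.mean(np.sum((fitted - A0) ** 2, axis=1))))
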