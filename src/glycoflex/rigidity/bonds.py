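"""Covalent and non-covalent interaction detection for the constraint network.

Covalent bonds are inferred from inter-atomic distances against covalent-radius
sums and classified as rotatable (5 bars) or non-rotatable (6 bars: peptide
bonds, double/partial-double bonds, planar side-chain groups, the porphyrin
of a haem group, calcium coordination). Hydrogen bonds are scored with a
Mayo-style 12-10 potential with hybridisation-dependent angular factors;
salt bridges receive a fixed strong energy so they survive every cutoff of a
rigidity dilution. Hydrophobic tethers join apolar carbon/sulfur atoms in
van der Waals contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, coords_array

__all__ = [
    "CovalentTopology",
    "HydrogenBond",
    "infer_covalent_bonds",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_tethers",
    "mayo_energy",
]

log = logging.getLogger(__name__)

#: single-bond covalent radii (Å)
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "FE": 1.32, "CA": 1.76, "ZN": 1.22, "MG": 1.41, "SE": 1.20,
}
#: van der Waals radii (Å) for tether and VDW-contact detection
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10, "P": 1.80,
             "FE": 2.00, "CA": 2.30}

_BOND_TOL = 0.4  # Å beyond radius sum
_BOND_MIN, _BOND_MAX = 0.7, 2.6  # Å, hard bond-length window

#: planar / conjugated side-chain groups whose internal bonds are locked
_PLANAR_GROUPS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
    "ASN": {"CG", "OD1", "ND2"},
    "GLN": {"CD", "OE1", "NE2"},
}

#: charged-group atoms for salt-bridge assignment
_CATION_ATOMS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}
_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass
class CovalentTopology:
    """Bonded atom-index pairs with a rotatable flag per bond."""

    bonds: list[tuple[int, int, bool]]  # (i, j, rotatable), i < j
    n_atoms: int = 0

    def neighbor_map(self) -> dict[int, set[int]]:
        nb: dict[int, set[int]] = {}
        for i, j, _ in self.bonds:
            nb.setdefault(i, set()).add(j)
            nb.setdefault(j, set()).add(i)
        return nb


def _is_rotatable(a: AtomRecord, b: AtomRecord) -> bool:
    # peptide bond C(i)-N(i+1): locked partial double bond
    if {a.name, b.name} == {"C", "N"} and a.residue_number != b.residue_number:
        return False
    # carbonyl / carboxyl / amide C=O within a residue
    if a.residue_number == b.residue_number:
        if {a.name, b.name} == {"C", "O"} or {a.name, b.name} == {"C", "OXT"}:
            return False
        grp = _PLANAR_GROUPS.get(a.residue_name)
        if grp and a.name in grp and b.name in grp:
            return False
        # haem porphyrin treated as one conjugated rigid unit
        if a.residue_name == "HEM":
            return False
    # calcium coordination locks the site (structural Ca2+ in peroxidases)
    if a.element == "CA" or b.element == "CA":
        return False
    return True


def infer_covalent_bonds(atoms: list[AtomRecord]) -> CovalentTopology:
    """Distance-based covalent bond inference with element-pair thresholds.

    A pair is bonded when its distance is within (r_cov(a)+r_cov(b)+0.4) Å,
    clipped to the 0.7–2.6 Å window. Hydrogens bond only to their nearest
    eligible heavy atom. Disulfides and metal coordination (haem Fe, Ca²⁺)
    fall out of the same rule via their radii.
    """
    xyz = coords_array(atoms)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=_BOND_MAX, output_type="ndarray")

    h_best: dict[int, tuple[float, int]] = {}  # hydrogen -> (dist, partner)
    bonds: list[tuple[int, int, bool]] = []
    for i, j in pairs:
        a, b = atoms[i], atoms[j]
        if a.element == "H" and b.element == "H":
            continue
        ra = COVALENT_RADII.get(a.element)
        rb = COVALENT_RADII.get(b.element)
        if ra is None or rb is None:
            log.warning("unknown element %s/%s; pair skipped", a.element, b.element)
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d < _BOND_MIN or d > min(ra + rb + _BOND_TOL, _BOND_MAX):
            continue
        if a.element == "H" or b.element == "H":
            h, heavy = (i, j) if a.element == "H" else (j, i)
            if h not in h_best or d < h_best[h][0]:
                h_best[h] = (d, heavy)
            continue
        bonds.append((int(min(i, j)), int(max(i, j)), _is_rotatable(a, b)))
    for h, (_, heavy) in h_best.items():
        i, j = min(h, heavy), max(h, heavy)
        bonds.append((int(i), int(j), _is_rotatable(atoms[i], atoms[j])))
    bonds.sort()
    return CovalentTopology(bonds=bonds, n_atoms=len(atoms))


@dataclass(frozen=True)
class HydrogenBond:
    donor: int
    hydrogen: int
    acceptor: int
    energy: float  # kcal/mol, <= 0 for accepted bonds


def mayo_energy(
    d_da: float,
    theta: float,
    phi: float | None,
    sp2_acceptor: bool,
    v0: float = 8.0,
    d0: float = 2.8,
) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol).

    E = V0·[5(d0/d)¹² − 6(d0/d)¹⁰]·F(θ)·G(φ) with the donor–acceptor
    distance d, the D–H···A angle θ and the H···A–B angle φ at the acceptor.
    F(θ) = cos²θ·exp(−(π−θ)⁶); G(φ) = cos²(φ−φ0) with φ0 = 120° for sp²
    acceptors and 109.5° for sp³ (G = 1 when the acceptor has no base atom).
    Angles in radians.
    """
    x = d0 / d_da
    radial = v0 * (5.0 * x**12 - 6.0 * x**10)
    f_theta = np.cos(theta) ** 2 * np.exp(-((np.pi - theta) ** 6))
    if phi is None:
        g_phi = 1.0
    else:
        phi0 = np.deg2rad(120.0 if sp2_acceptor else 109.5)
        g_phi = np.cos(phi - phi0) ** 2
    return float(radial * f_theta * g_phi)


def _angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    v1, v2 = p1 - p2, p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def detect_hydrogen_bonds(
    atoms: list[AtomRecord],
    topology: CovalentTopology,
    max_da: float = 4.0,
    salt_bridge_energy: float = -10.0,
) -> list[HydrogenBond]:
    """Geometric D–H···A detection scored by the Mayo-style potential.

    Donors are N/O/S atoms carrying a bonded hydrogen (donors without one
    are skipped with a log entry); acceptors are O/S atoms and bare
    ring nitrogens. Candidates require d(D,A) ≤ 4 Å and θ > 90°; only
    energies < 0 are kept. Salt bridges between Arg/Lys and Asp/Glu charged
    groups are assigned a fixed −10 kcal/mol.
    """
    xyz = coords_array(atoms)
    nb = topology.neighbor_map()

    def hydrogens_of(i):
        return [j for j in nb.get(i, ()) if atoms[j].element == "H"]

    def heavy_neighbors(i):
        return [j for j in nb.get(i, ()) if atoms[j].element != "H"]

    donors = []
    for i, a in enumerate(atoms):
        if a.element in ("N", "O", "S"):
            hs = hydrogens_of(i)
            if hs:
                donors.append((i, hs))
            elif a.element == "N" and len(nb.get(i, ())) >= 3:
                log.debug("donor %s%d/%s has no hydrogen; skipped",
                          a.residue_name, a.residue_number, a.name)

    acceptors = []
    for i, a in enumerate(atoms):
        if a.element in ("O", "S"):
            acceptors.append(i)
        elif a.element == "N" and not hydrogens_of(i) and len(nb.get(i, ())) <= 2:
            acceptors.append(i)  # e.g. His ND1 free tautomer
    if not donors or not acceptors:
        return []

    acc_xyz = xyz[acceptors]
    tree = cKDTree(acc_xyz)
    out: list[HydrogenBond] = []
    for d_idx, hs in donors:
        near = tree.query_ball_point(xyz[d_idx], max_da)
        best: dict[int, HydrogenBond] = {}
        for k in near:
            a_idx = acceptors[k]
            if a_idx == d_idx or a_idx in nb.get(d_idx, ()):
                continue
            # skip 1-3 pairs (shared covalent neighbour)
            if nb.get(d_idx, set()) & nb.get(a_idx, set()):
                continue
            d_da = float(np.linalg.norm(xyz[d_idx] - xyz[a_idx]))
            acc = atoms[a_idx]
            heavy_nb = heavy_neighbors(a_idx)
            sp2 = acc.element == "N" or (
                acc.element == "O" and len(heavy_nb) == 1 and not hydrogens_of(a_idx)
            )
            for h_idx in hs:
                theta = _angle(xyz[d_idx], xyz[h_idx], xyz[a_idx])
                if theta <= np.pi / 2:  # bent beyond 90 deg: rejected
                    continue
                if heavy_nb:
                    phi = _angle(xyz[h_idx], xyz[a_idx], xyz[heavy_nb[0]])
                else:
                    phi = None
                is_salt = (
                    (atoms[d_idx].residue_name, atoms[d_idx].name) in _CATION_ATOMS
                    and (acc.residue_name, acc.name) in _ANION_ATOMS
                )
                if is_salt:
                    e = salt_bridge_energy
                else:
                    e = mayo_energy(d_da, theta, phi, sp2)
                if e < 0 and (a_idx not in best or e < best[a_idx].energy):
                    best[a_idx] = HydrogenBond(d_idx, h_idx, a_idx, e)
        out.extend(best.values())
    out.sort(key=lambda hb: (hb.donor, hb.acceptor))
    return out


def _graph_separation_leq(nb: dict[int, set[int]], i: int, j: int, k: int) -> bool:
    """True if atoms i and j are within k covalent bonds of each other."""
    frontier = {i}
    seen = {i}
    for _ in range(k):
        frontier = {n for f in frontier for n in nb.get(f, ())} - seen
        if j in frontier:
            return True
        seen |= frontier
    return False


def detect_hydrophobic_tethers(
    atoms: list[AtomRecord],
    topology: CovalentTopology | None = None,
    gap: float = 0.25,
) -> list[tuple[int, int]]:
    """Apolar C/S atom pairs in van der Waals contact (sum of radii + 0.25 Å).

    Atoms covalently bonded to N or O are considered polarised and excluded,
    as are intra-residue pairs and pairs within three covalent bonds.
    """
    if topology is None:
        from .bonds import infer_covalent_bonds as _icb  # self-import guard

        topology = _icb(atoms)
    nb = topology.neighbor_map()
    xyz = coords_array(atoms)

    def apolar(i):
        a = atoms[i]
        if a.element not in ("C", "S"):
            return False
        return not any(atoms[j].element in ("N", "O") for j in nb.get(i, ()))

    cand = [i for i in range(len(atoms)) if apolar(i)]
    if not cand:
        return []
    tree = cKDTree(xyz[cand])
    max_r = 2 * VDW_RADII["S"] + gap
    tethers = []
    for ii, jj in tree.query_pairs(r=max_r):
        i, j = cand[ii], cand[jj]
        a, b = atoms[i], atoms[j]
        if (a.chain, a.residue_number) == (b.chain, b.residue_number):
            continue
        cut = VDW_RADII[a.element] + VDW_RADII[b.element] + gap
        if np.linalg.norm(xyz[i] - xyz[j]) > cut:
            continue
        if _graph_separation_leq(nb, i, j, 3):
            continue
        tethers.append((min(i, j), max(i, j)))
    tethers.sort()
    return tethers
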