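"""Conformational-ensemble post-processing and network differencing.

Multi-model PDB ensembles (e.g. trajectories exported frame-by-frame) are
superposed, reduced to per-residue Cα RMSF profiles, residue minimum-distance
matrices and per-frame interaction records, and two conditions are compared
by differencing:

* ΔRMSF with a relative significance rule (|Δ| above 10% of the maximal
  |Δ| across residues);
* distance-difference networks restricted to pairs within a 5.5 Å contact
  cutoff, with long-range (> i+4 in sequence) flagging;
* interaction-frequency differences retained when the frequency changed by
  more than ±10%.

The interaction classifier is a deliberately simple geometric stand-in for
a full interaction-typing engine: hydrogen bonds, van der Waals contacts,
salt bridges and π–π stacks from distance/angle criteria.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

__all__ = [
    "Ensemble",
    "RMSFProfile",
    "DeltaRMSF",
    "DistanceDiffEdge",
    "InteractionRecord",
    "read_ensemble",
    "write_ensemble",
    "superpose",
    "compute_rmsf",
    "delta_rmsf",
    "residue_min_distance_matrix",
    "distance_diff_network",
    "interaction_frequencies",
    "interaction_diff",
]

log = logging.getLogger(__name__)

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}


@dataclass
class Ensemble:
    """Frames over a fixed atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3); the remaining arrays are
    per-atom annotations shared by all frames.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.n_frames < 2:
            raise ValueError("an ensemble needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue numbers in roster order."""
        _, idx = np.unique(self.residue_numbers, return_index=True)
        return self.residue_numbers[np.sort(idx)]

    def ca_mask(self) -> np.ndarray:
        return (self.atom_names == "CA") & (self.elements == "C")


def read_ensemble(pdb_text: str) -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL blocks) into an Ensemble.

    All models must share an identical atom roster; a mismatch is rejected
    naming the offending model.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    if n_models < 2:
        raise ValueError(f"need at least 2 models, found {n_models}")
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        # locate the first inconsistent model for the error message
        ref = pdb.get_structure(model=1)
        for m in range(2, n_models + 1):
            arr = pdb.get_structure(model=m)
            if arr.array_length() != ref.array_length():
                raise ValueError(
                    f"model {m} has {arr.array_length()} atoms, "
                    f"model 1 has {ref.array_length()}"
                ) from exc
        raise ValueError(f"inconsistent models: {exc}") from exc
    return Ensemble(
        coords=np.asarray(stack.coord, float),
        atom_names=np.asarray(stack.atom_name),
        elements=np.char.upper(np.asarray(stack.element, dtype=str)),
        residue_numbers=np.asarray(stack.res_id),
        residue_names=np.asarray(stack.res_name),
        chains=np.asarray(stack.chain_id),
    )


def write_ensemble(ens: Ensemble) -> str:
    """Serialise an ensemble to multi-model PDB text."""
    import biotite.structure as struc

    stack = struc.AtomArrayStack(ens.n_frames, ens.n_atoms)
    stack.coord = ens.coords
    stack.atom_name = ens.atom_names
    stack.element = ens.elements
    stack.res_id = ens.residue_numbers
    stack.res_name = ens.residue_names
    stack.chain_id = ens.chains
    stack.hetero = np.zeros(ens.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising ||mobile@R + t − target||."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, tc - mc @ rot


def superpose(ens: Ensemble, reference_frame: int = 0, selection: np.ndarray | None = None) -> Ensemble:
    """Least-squares superpose every frame onto the reference over a selection
    (default: Cα atoms). Needs at least 3 selected atoms."""
    sel = ens.ca_mask() if selection is None else np.asarray(selection, bool)
    if sel.sum() < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = ens.coords[reference_frame][sel]
    out = np.empty_like(ens.coords)
    for f in range(ens.n_frames):
        rot, t = _kabsch(ens.coords[f][sel], ref)
        out[f] = ens.coords[f] @ rot + t
    return Ensemble(
        coords=out,
        atom_names=ens.atom_names,
        elements=ens.elements,
        residue_numbers=ens.residue_numbers,
        residue_names=ens.residue_names,
        chains=ens.chains,
    )


@dataclass
class RMSFProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # Å, per Cα

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_ids, "rmsf_A": self.rmsf})


def compute_rmsf(ens: Ensemble) -> RMSFProfile:
    """Cα RMSF per residue: sqrt(mean over frames of the squared deviation
    from the frame-mean position). Residues without a Cα are skipped."""
    mask = ens.ca_mask()
    if not mask.any():
        raise ValueError("no Cα atoms in ensemble")
    residues_with_ca = ens.residue_numbers[mask]
    missing = set(ens.residue_ids.tolist()) - set(residues_with_ca.tolist())
    if missing:
        log.warning("residues without Cα skipped: %s", sorted(missing))
    xyz = ens.coords[:, mask, :]  # (frames, n_ca, 3)
    dev = xyz - xyz.mean(axis=0, keepdims=True)
    rmsf = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return RMSFProfile(residue_ids=residues_with_ca, rmsf=rmsf)


@dataclass
class DeltaRMSF:
    """Profile difference a − b (convention: unglycosylated minus
    glycosylated, so positive deltas mean less flexible on glycosylation)."""

    residue_ids: np.ndarray
    delta: np.ndarray
    threshold: float
    significant_less_flexible: set[int] = field(default_factory=set)
    significant_more_flexible: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "delta_rmsf_A": self.delta,
                "significant_less_flexible": [
                    int(r) in self.significant_less_flexible for r in self.residue_ids
                ],
                "significant_more_flexible": [
                    int(r) in self.significant_more_flexible for r in self.residue_ids
                ],
            }
        )


def delta_rmsf(a: RMSFProfile, b: RMSFProfile, threshold_frac: float = 0.10) -> DeltaRMSF:
    """Difference two RMSF profiles with the relative significance rule.

    The threshold is ``threshold_frac`` of the maximal |Δ|; residues above
    +threshold are significantly less flexible in condition b, below
    −threshold significantly more flexible (disjoint sets by construction).
    """
    if not np.array_equal(a.residue_ids, b.residue_ids):
        raise ValueError("profiles cover different residue rosters")
    delta = a.rmsf - b.rmsf
    thr = threshold_frac * float(np.max(np.abs(delta))) if delta.size else 0.0
    less = {int(r) for r, d in zip(a.residue_ids, delta) if d > thr > 0}
    more = {int(r) for r, d in zip(a.residue_ids, delta) if d < -thr < 0}
    return DeltaRMSF(
        residue_ids=a.residue_ids,
        delta=delta,
        threshold=thr,
        significant_less_flexible=less,
        significant_more_flexible=more,
    )


def residue_min_distance_matrix(
    ens: Ensemble, mode: str = "mean_of_frame_minima", ca_only: bool = False
) -> pd.DataFrame:
    """Trajectory-aggregated smallest inter-residue distance matrix (Å).

    Per frame the minimum heavy-atom (or Cα–Cα with ``ca_only``) distance is
    taken for each residue pair, then aggregated across frames by the mean
    (default, mirroring per-frame-minimum averaging) or the overall minimum
    (``mode='min'``). Returned as a symmetric, zero-diagonal DataFrame
    indexed by residue number.
    """
    if mode not in ("mean_of_frame_minima", "min"):
        raise ValueError("mode must be 'mean_of_frame_minima' or 'min'")
    if ca_only:
        keep = ens.ca_mask()
    else:
        keep = ens.elements != "H"
    res = ens.residue_numbers[keep]
    res_ids = ens.residue_ids
    n = res_ids.size
    groups = [np.flatnonzero(res == r) for r in res_ids]

    agg = np.zeros((n, n))
    for f in range(ens.n_frames):
        xyz = ens.coords[f][keep]
        d = cdist(xyz, xyz)
        frame_min = np.zeros((n, n))
        for i in range(n):
            gi = groups[i]
            for j in range(i + 1, n):
                m = d[np.ix_(gi, groups[j])].min()
                frame_min[i, j] = frame_min[j, i] = m
        if mode == "min":
            agg = frame_min if f == 0 else np.minimum(agg, frame_min)
        else:
            agg += frame_min
    if mode == "mean_of_frame_minima":
        agg /= ens.n_frames
    np.fill_diagonal(agg, 0.0)
    return pd.DataFrame(agg, index=res_ids, columns=res_ids)


@dataclass(frozen=True)
class DistanceDiffEdge:
    residue_i: int
    residue_j: int
    delta_distance: float  # Å, condition A minus condition B
    long_range: bool  # sequence separation > i+4
    closer_in: str  # "A", "B" or "none"


def distance_diff_network(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    cutoff: float = 5.5,
    min_sep: int = 4,
    closer_threshold: float = 0.3,
    require_both: bool = False,
) -> list[DistanceDiffEdge]:
    """Edges where residue pairs in contact change distance between conditions.

    Pairs within ``cutoff`` in either condition (both, when ``require_both``)
    are kept; Δ = A − B, classified closer-in-B for Δ > threshold and
    closer-in-A for Δ < −threshold. ``long_range`` flags sequence separation
    greater than ``min_sep``.
    """
    if mat_a.shape != mat_b.shape or not np.array_equal(mat_a.index, mat_b.index):
        raise ValueError("matrices must share shape and residue index")
    res = mat_a.index.to_numpy()
    a, b = mat_a.to_numpy(), mat_b.to_numpy()
    edges = []
    for i in range(res.size):
        for j in range(i + 1, res.size):
            within = (a[i, j] <= cutoff) and (b[i, j] <= cutoff) if require_both else (
                (a[i, j] <= cutoff) or (b[i, j] <= cutoff)
            )
            if not within:
                continue
            delta = float(a[i, j] - b[i, j])
            if delta > closer_threshold:
                closer = "B"
            elif delta < -closer_threshold:
                closer = "A"
            else:
                closer = "none"
            edges.append(
                DistanceDiffEdge(
                    residue_i=int(res[i]),
                    residue_j=int(res[j]),
                    delta_distance=delta,
                    long_range=bool(abs(int(res[j]) - int(res[i])) > min_sep),
                    closer_in=closer,
                )
            )
    return edges


@dataclass(frozen=True)
class InteractionRecord:
    residue_i: int
    residue_j: int
    kind: str  # HBOND | VDW | PIPISTACK | IONIC
    frequency: float  # fraction of frames in [0, 1]


_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_CATIONS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}
_ANIONS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def _frame_interactions(ens: Ensemble, f: int, hbond_enabled: bool) -> set[tuple[int, int, str]]:
    """Classify residue-pair interactions in one frame.

    HBOND: N/O/S donor with H, D–A ≤ 3.5 Å and D–H···A angle ≥ 120°.
    VDW: heavy-atom distance ≤ vdW-radius sum + 0.5 Å (non-adjacent residues).
    IONIC: opposite charged-group centroids ≤ 4.0 Å.
    PIPISTACK: aromatic ring centroids ≤ 5.5 Å, plane angle ≤ 30° or ≥ 150°.
    """
    xyz = ens.coords[f]
    res = ens.residue_numbers
    names = ens.atom_names
    elements = ens.elements
    resnames = ens.residue_names
    found: set[tuple[int, int, str]] = set()

    heavy = np.flatnonzero(elements != "H")
    d_heavy = cdist(xyz[heavy], xyz[heavy])
    for ii in range(heavy.size):
        for jj in range(ii + 1, heavy.size):
            i, j = heavy[ii], heavy[jj]
            ri, rj = int(res[i]), int(res[j])
            if abs(ri - rj) < 1 or ri == rj:
                continue
            cut = _VDW.get(elements[i], 1.7) + _VDW.get(elements[j], 1.7) + 0.5
            if d_heavy[ii, jj] <= cut and abs(ri - rj) > 1:
                found.add((min(ri, rj), max(ri, rj), "VDW"))

    if hbond_enabled:
        h_idx = np.flatnonzero(elements == "H")
        don_idx = np.flatnonzero(np.isin(elements, ("N", "O", "S")))
        for h in h_idx:
            # hydrogen's donor: nearest N/O/S within bonding distance
            dd = np.linalg.norm(xyz[don_idx] - xyz[h], axis=1)
            if dd.size == 0 or dd.min() > 1.3:
                continue
            d_atom = don_idx[int(np.argmin(dd))]
            for a_atom in don_idx:
                ra, rd = int(res[a_atom]), int(res[d_atom])
                if a_atom == d_atom or ra == rd:
                    continue
                d_da = np.linalg.norm(xyz[d_atom] - xyz[a_atom])
                if d_da > 3.5:
                    continue
                v1 = xyz[d_atom] - xyz[h]
                v2 = xyz[a_atom] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang >= 120.0:
                    found.add((min(rd, ra), max(rd, ra), "HBOND"))

    # ionic: charged-group centroids
    groups: dict[tuple[int, int], list[int]] = {}  # (res, sign) -> atom idx
    for i in range(ens.n_atoms):
        key = (str(resnames[i]), str(names[i]))
        if key in _CATIONS:
            groups.setdefault((int(res[i]), +1), []).append(i)
        elif key in _ANIONS:
            groups.setdefault((int(res[i]), -1), []).append(i)
    keys = list(groups)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            (ra, sa), (rb, sb) = keys[a], keys[b]
            if sa * sb >= 0 or ra == rb:
                continue
            ca = xyz[groups[keys[a]]].mean(axis=0)
            cb = xyz[groups[keys[b]]].mean(axis=0)
            if np.linalg.norm(ca - cb) <= 4.0:
                found.add((min(ra, rb), max(ra, rb), "IONIC"))

    # pi-pi stacking: ring centroid distance and plane angle
    rings: list[tuple[int, np.ndarray, np.ndarray]] = []
    for rid in np.unique(res):
        sel = res == rid
        rn = str(resnames[sel][0])
        ring_names = _RING_ATOMS.get(rn)
        if not ring_names:
            continue
        idx = [
            int(k)
            for k in np.flatnonzero(sel)
            if names[k] in ring_names
        ]
        if len(idx) < 5:
            continue
        pts = xyz[idx]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        rings.append((int(rid), centroid, vt[2]))
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            ra, ca, na = rings[a]
            rb, cb, nb_ = rings[b]
            if np.linalg.norm(ca - cb) > 5.5:
                continue
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(na, nb_)), 0, 1)))
            if ang <= 30.0:  # |cos| folds >=150 onto <=30
                found.add((min(ra, rb), max(ra, rb), "PIPISTACK"))
    return found


def interaction_frequencies(ens: Ensemble) -> list[InteractionRecord]:
    """Per-frame geometric interaction typing aggregated to frequencies.

    frequency = frames containing the (pair, type) interaction / total
    frames. Hydrogen-bond typing is disabled with a warning when the
    ensemble carries no hydrogens.
    """
    hbond_enabled = bool(np.any(ens.elements == "H"))
    if not hbond_enabled:
        log.warning("no hydrogens in ensemble; HBOND typing disabled")
    counts: dict[tuple[int, int, str], int] = {}
    for f in range(ens.n_frames):
        for key in _frame_interactions(ens, f, hbond_enabled):
            counts[key] = counts.get(key, 0) + 1
    return [
        InteractionRecord(i, j, kind, c / ens.n_frames)
        for (i, j, kind), c in sorted(counts.items())
    ]


def interaction_diff(
    rec_a: list[InteractionRecord],
    rec_b: list[InteractionRecord],
    threshold: float = 0.10,
) -> list[tuple[int, int, str, float, float, float]]:
    """Retain (pair, type) records whose frequency changed by more than
    ±threshold; a record missing on one side counts as frequency 0.

    Returns tuples (res_i, res_j, type, freq_a, freq_b, delta) with
    delta = freq_a − freq_b.
    """
    fa = {(r.residue_i, r.residue_j, r.kind): r.frequency for r in rec_a}
    fb = {(r.residue_i, r.residue_j, r.kind): r.frequency for r in rec_b}
    out = []
    for key in sorted(set(fa) | set(fb)):
        va, vb = fa.get(key, 0.0), fb.get(key, 0.0)
        if abs(va - vb) > threshold:
            out.append((*key, va, vb, va - vb))
    return out
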