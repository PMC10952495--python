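"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with its
generating parameters returned alongside, so each stage supports parameter-
recovery testing without any external data:

* REES datasets: two-component skewed-Gaussian emission spectra whose
  tryptophan-component CSM follows CSM0 + A·exp(R·Δλ_Ex) over the
  292–310 nm excitation grid (emission 315–500 nm);
* CD thermal melts from the two-state model with sloping baselines over
  300–370 K;
* Michaelis–Menten rate tables (0.1–4.0 mM substrate, triplicates) and
  MMRT-curved ln kcat vs T series (293–313 K), defaulting to the published
  HRP parameter sets;
* protonated toy helical peptides with designed backbone hydrogen-bond
  energies and an optional rigid bridging ligand for rigidity testing;
* Gaussian-fluctuation multi-model ensembles with prescribed per-residue
  amplitudes and scripted interaction motifs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import MMRTFit, RateTable, TempRateSeries, eval_mmrt
from .melt import MeltCurve, two_state_model
from .rigidity.structure import AtomRecord
from .spectra import EmissionSpectrum, SkewedGaussian, compute_csm

__all__ = [
    "gen_rees_dataset",
    "gen_melt_curve",
    "gen_kinetics",
    "gen_toy_structure",
    "gen_toy_ensemble",
    "ScriptedMotif",
    "EXCITATION_GRID",
    "EMISSION_GRID",
]

#: default grids matching the measurement protocols
EXCITATION_GRID = np.arange(292.0, 310.1, 1.0)
EMISSION_GRID = np.arange(315.0, 500.1, 1.0)


# --------------------------------------------------------------------------
# REES spectra
# --------------------------------------------------------------------------

def _solve_lambda_max(target_csm: float, f_max: float, w: float, b: float,
                      grid: np.ndarray) -> float:
    """λmax such that the component's grid CSM equals ``target_csm``.

    Grid truncation makes CSM(λmax) slightly nonlinear, so invert it
    numerically (CSM is strictly increasing in λmax)."""
    from scipy.optimize import brentq

    def g(lam):
        return compute_csm(SkewedGaussian(f_max, lam, w, b), grid) - target_csm

    return float(brentq(g, grid[0] - 50.0, grid[-1] + 50.0, xtol=1e-10))


def gen_rees_dataset(
    seed: int,
    csm0: float = 345.0,
    a: float = 1.5,
    r: float = 0.12,
    excitation: np.ndarray = EXCITATION_GRID,
    emission: np.ndarray = EMISSION_GRID,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    trp_shape: tuple[float, float, float] = (1.0, 60.0, 0.4),
    second_component: SkewedGaussian | None = SkewedGaussian(0.30, 430.0, 80.0, 0.2),
) -> tuple[list[EmissionSpectrum], dict]:
    """Spectra whose trp-component CSM follows the REES exponential.

    ``trp_shape`` fixes (f_max, w, b) of the tryptophan component; its λmax
    is solved per excitation so the component CSM on the emission grid equals
    CSM0 + A·exp(R·Δλ_Ex) exactly. Additive Gaussian noise of ``noise_sd``
    (a.u.) is applied per replicate.
    """
    rng = np.random.default_rng(seed)
    f_max, w, b = trp_shape
    spectra: list[EmissionSpectrum] = []
    lambda_maxes = []
    for ex in excitation:
        dlx = ex - excitation[0]
        target = csm0 + a * np.exp(r * dlx)
        lam = _solve_lambda_max(target, f_max, w, b, emission)
        lambda_maxes.append(lam)
        trp = SkewedGaussian(f_max, lam, w, b)
        clean = trp(emission)
        if second_component is not None:
            clean = clean + second_component(emission)
        for rep in range(n_replicates):
            y = clean + rng.normal(0.0, noise_sd, emission.size) if noise_sd > 0 else clean
            spectra.append(
                EmissionSpectrum(
                    excitation_wavelength=float(ex),
                    emission_wavelengths=emission.copy(),
                    intensities=np.clip(y, 0.0, None),
                    replicate_id=str(rep),
                )
            )
    truth = {
        "csm0": csm0, "a": a, "r": r, "a_over_r": a / r if r else None,
        "trp_f_max": f_max, "trp_w": w, "trp_b": b,
        "trp_lambda_max": lambda_maxes,
        "noise_sd": noise_sd, "n_replicates": n_replicates, "seed": seed,
    }
    return spectra, truth


# --------------------------------------------------------------------------
# thermal melts
# --------------------------------------------------------------------------

def gen_melt_curve(
    seed: int,
    tm: float = 350.8,
    dh_vh: float = 450.0,
    bf: float = 0.0,
    mf: float = 8e-4,
    bu: float = 1.0,
    mu: float = 1.5e-3,
    t_range: tuple[float, float] = (300.0, 370.0),
    n_points: int = 60,
    noise_frac: float = 0.0,
) -> tuple[MeltCurve, dict]:
    """Two-state melt with sloping baselines; defaults to the holo-pHRP
    midpoint (350.8 K) with a Van't Hoff enthalpy typical of a ~34 kDa
    glycoprotein. Noise is Gaussian with sd = noise_frac × signal range."""
    rng = np.random.default_rng(seed)
    t = np.linspace(*t_range, n_points)
    clean = two_state_model(t, tm, dh_vh, bf, mf, bu, mu)
    sd = noise_frac * float(np.ptp(clean)) if noise_frac > 0 else 0.0
    y = clean + rng.normal(0.0, sd, t.size) if sd > 0 else clean
    truth = {"tm": tm, "dh_vh": dh_vh, "bf": bf, "mf": mf, "bu": bu, "mu": mu,
             "noise_frac": noise_frac, "seed": seed}
    return MeltCurve(t, y), truth


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

def gen_kinetics(
    seed: int,
    kcat: float = 917.0,
    km: float = 0.92,
    mmrt: tuple[float, float, float, float] = (1.3, 1.13, -1.9, 298.0),
    substrate_mM: np.ndarray | None = None,
    n_replicates: int = 3,
    mm_noise_frac: float = 0.0,
    temperatures: np.ndarray | None = None,
    k_noise_frac: float = 0.0,
) -> tuple[RateTable, TempRateSeries, dict]:
    """Michaelis–Menten rate table plus MMRT temperature series.

    Defaults are the published pHRP parameters: kcat 917 s⁻¹, KM 0.92 mM and
    (ΔH‡, ΔS‡, ΔCp‡, T0) = (1.3, 1.13, −1.9, 298). Substrate spans
    0.1–4.0 mM in triplicate; temperatures span 293–313 K. Noise is
    multiplicative Gaussian of the given fraction.
    """
    rng = np.random.default_rng(seed)
    if substrate_mM is None:
        substrate_mM = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
    s = np.repeat(substrate_mM, n_replicates)
    v = kcat * s / (km + s)
    if mm_noise_frac > 0:
        v = v * (1.0 + rng.normal(0.0, mm_noise_frac, v.size))
    table = RateTable(substrate_mM=s, rate_s=np.clip(v, 0.0, None),
                      replicate=np.tile(np.arange(n_replicates), substrate_mM.size))

    dh, ds, dcp, t0 = mmrt
    if temperatures is None:
        temperatures = np.linspace(293.0, 313.0, 9)
    lnk = eval_mmrt(MMRTFit(dh, ds, dcp, t0), temperatures)
    k = np.exp(lnk)
    if k_noise_frac > 0:
        k = k * (1.0 + rng.normal(0.0, k_noise_frac, k.size))
    series = TempRateSeries(temperature=temperatures, kcat=np.clip(k, 1e-12, None))

    truth = {"kcat": kcat, "km": km, "dh_t0": dh, "ds_t0": ds, "dcp": dcp, "t0": t0,
             "mm_noise_frac": mm_noise_frac, "k_noise_frac": k_noise_frac, "seed": seed}
    return table, series, truth


# --------------------------------------------------------------------------
# toy structures for rigidity analysis
# --------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d bonded to c."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(angle),
        length * np.sin(angle) * np.cos(dihedral),
        length * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_toy_structure(
    seed: int = 0,
    n_residues: int = 15,
    designed_energies: list[float] | None = None,
    with_ligand: bool = False,
    ligand_span: tuple[int, int] | None = None,
    glyco_sites: tuple[int, ...] | None = None,
    phi: float = -57.0,
    psi: float = -47.0,
) -> tuple[list[AtomRecord], dict]:
    """Ideal α-helical alanine peptide with backbone amide hydrogens.

    Backbone i→i+4 N–H···O hydrogen bonds arise from the helical geometry;
    ``designed_energies`` (cycled over the bonds in order of acceptor
    residue) populate the returned energy-override table so a rigidity
    dilution breaks the helix at exactly the designed cutoffs. With
    ``with_ligand`` a rigid all-carbon "HEM" ligand is laid alongside the
    helix in van der Waals contact with the Cβ atoms, bridging the chain
    with hydrophobic tethers.

    Returns the atom list and a truth record containing the H-bond
    energy-override table (keys: donor_resnum, donor_atom, acceptor_resnum,
    acceptor_atom).
    """
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([1.458, 0.0, 0.0])
    c_pos = _place_atom(n_pos + np.array([0, 1, 0]), n_pos, ca_pos, 1.525, 111.2, 0.0)

    backbone: list[dict] = []
    prev = {"N": n_pos, "CA": ca_pos, "C": c_pos}
    for i in range(n_residues):
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res.update(prev)
        else:
            res["N"] = _place_atom(backbone[-1]["N"], backbone[-1]["CA"],
                                   backbone[-1]["C"], 1.329, 116.2, psi)
            res["CA"] = _place_atom(backbone[-1]["CA"], backbone[-1]["C"],
                                    res["N"], 1.458, 121.7, 180.0)
            res["C"] = _place_atom(backbone[-1]["C"], res["N"], res["CA"],
                                   1.525, 111.2, phi)
        backbone.append(res)
    for i, res in enumerate(backbone):
        if i + 1 < n_residues:
            nxt = backbone[i + 1]["N"]
            res["O"] = _place_atom(nxt, res["CA"], res["C"], 1.231, 122.5, 180.0)
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.5, psi + 180.0)
        # amide hydrogen: in-plane, roughly anti to the bisector of N's bonds
        if i > 0:
            u1 = res["CA"] - res["N"]
            u2 = backbone[i - 1]["C"] - res["N"]
            bis = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            res["H"] = res["N"] - 1.01 * bis / np.linalg.norm(bis)
        # Cβ: tetrahedral branch off CA
        res["CB"] = _place_atom(res["N"], res["C"], res["CA"], 1.53, 110.5, 122.5)

    atoms: list[AtomRecord] = []
    serial = 0
    order = ("N", "CA", "C", "O", "CB", "H")
    for i, res in enumerate(backbone):
        for name in order:
            if name not in res:
                continue
            serial += 1
            element = "H" if name == "H" else ("N" if name == "N" else
                                               "O" if name == "O" else "C")
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element, residue_name="ALA",
                residue_number=i + 1, chain="A",
                coords=tuple(round(float(x), 3) for x in res[name]),
            ))

    # designed energies for the helical i -> i+4 hydrogen bonds
    energy_table: dict[tuple[int, str, int, str], float] = {}
    hbond_pairs = [(i + 5, i + 1) for i in range(n_residues - 4)]  # donor N(i+4), acceptor O(i)
    if designed_energies:
        for k, (don, acc) in enumerate(hbond_pairs):
            energy_table[(don, "N", acc, "O")] = float(
                designed_energies[k % len(designed_energies)]
            )

    if with_ligand:
        cb = {a.residue_number: np.array(a.coords)
              for a in atoms if a.name == "CB"}
        centroid_axis = np.array([np.array(a.coords) for a in atoms if a.name == "CA"])
        axis_dir = centroid_axis[-1] - centroid_axis[0]
        axis_dir /= np.linalg.norm(axis_dir)
        # polyline of carbons hugging the CB atoms at tether range
        lo, hi = ligand_span if ligand_span is not None else (2, n_residues - 1)
        waypoints = []
        for rnum in range(lo, hi + 1):
            p = cb[rnum]
            outward = p - centroid_axis.mean(axis=0)
            outward -= np.dot(outward, axis_dir) * axis_dir
            outward /= np.linalg.norm(outward)
            waypoints.append(p + 3.2 * outward)
        path = [waypoints[0]]
        for w in waypoints[1:]:
            while np.linalg.norm(w - path[-1]) > 1.5:
                step = w - path[-1]
                path.append(path[-1] + 1.45 * step / np.linalg.norm(step))
            path.append(w)
        lig_res = n_residues + 1
        for k, p in enumerate(path):
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=f"C{k + 1}", element="C", residue_name="HEM",
                residue_number=lig_res, chain="A",
                coords=tuple(round(float(x), 3) for x in p), is_hetero=True,
            ))

    truth = {
        "n_residues": n_residues,
        "hbond_pairs": hbond_pairs,
        "energy_table": energy_table,
        "glyco_sites": tuple(glyco_sites) if glyco_sites else (),
        "with_ligand": with_ligand,
        "seed": seed,
    }
    return atoms, truth


# --------------------------------------------------------------------------
# toy ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptedMotif:
    """An interaction motif present in a prescribed fraction of frames.

    ``kind`` ∈ {HBOND, VDW, IONIC, PIPISTACK}; the motif occupies two extra
    residues appended after the backbone, brought into interaction geometry
    in exactly round(fraction × n_frames) frames (the first ones, shuffled
    by the generator seed) and separated otherwise.
    """

    kind: str
    fraction: float


def _motif_atoms(kind: str, res_i: int, res_j: int, origin: np.ndarray):
    """Atom specs (name, element, resname, resnum, offset-in-'on'-geometry,
    offset-in-'off'-geometry) for one motif pair."""
    sep_off = np.array([12.0, 0.0, 0.0])
    if kind == "IONIC":
        on = {
            ("NZ", "N", "LYS", res_i): np.zeros(3),
            ("OD1", "O", "ASP", res_j): np.array([3.4, 0.4, 0.0]),
            ("OD2", "O", "ASP", res_j): np.array([3.4, -0.4, 0.0]),
        }
    elif kind == "VDW":
        on = {
            ("CB", "C", "ALA", res_i): np.zeros(3),
            ("CB", "C", "ALA", res_j): np.array([3.5, 0.0, 0.0]),
        }
    elif kind == "HBOND":
        on = {
            ("O", "O", "GLY", res_i): np.zeros(3),
            ("H", "H", "GLY", res_j): np.array([1.9, 0.0, 0.0]),
            ("N", "N", "GLY", res_j): np.array([2.9, 0.0, 0.0]),
        }
    elif kind == "PIPISTACK":
        ring = []
        for k in range(6):
            ang = np.pi * k / 3.0
            ring.append(1.39 * np.array([np.cos(ang), np.sin(ang), 0.0]))
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        on = {(names[k], "C", "PHE", res_i): ring[k] for k in range(6)}
        for k in range(6):
            on[(names[k], "C", "PHE", res_j)] = ring[k] + np.array([0.0, 0.0, 4.0])
    else:
        raise ValueError(f"unknown motif kind {kind}")
    out = []
    for (name, element, resname, resnum), off in on.items():
        off_pos = off + (sep_off if resnum == res_j else 0.0)
        out.append((name, element, resname, resnum, origin + off, origin + off_pos))
    return out


def gen_toy_ensemble(
    seed: int,
    n_residues: int = 10,
    n_frames: int = 200,
    sigma: np.ndarray | float = 0.5,
    base_coords: np.ndarray | None = None,
    motifs: list[ScriptedMotif] | None = None,
) -> tuple["np.ndarray", dict]:
    """Gaussian-fluctuation Cα ensemble with optional scripted motifs.

    The backbone is a Cα-only glycine chain (3.8 Å spacing, or explicit
    ``base_coords``); each frame displaces every residue independently by a
    per-axis Gaussian of sd σᵢ, so the expected Cα RMSF is σᵢ·√3 (per-axis
    convention). Motif residues are appended after the chain.

    Returns an :class:`~glycoflex.ensembles.Ensemble` and the truth record.
    """
    from .ensembles import Ensemble

    rng = np.random.default_rng(seed)
    sigma = np.broadcast_to(np.asarray(sigma, float), (n_residues,)).copy()
    if base_coords is None:
        base_coords = np.zeros((n_residues, 3))
        base_coords[:, 0] = 3.8 * np.arange(n_residues)
    base_coords = np.asarray(base_coords, float)

    names = ["CA"] * n_residues
    elements = ["C"] * n_residues
    resnums = list(range(1, n_residues + 1))
    resnames = ["GLY"] * n_residues
    atom_res_index = list(range(n_residues))  # residue index for displacement

    motif_truth = []
    motif_atom_specs = []  # (on_pos, off_pos) per atom
    next_res = n_residues + 1
    for m_idx, motif in enumerate(motifs or []):
        origin = np.array([0.0, 15.0 + 25.0 * m_idx, 0.0])
        # non-adjacent numbering so contact classifiers treating sequence
        # neighbours as trivial still see the motif
        res_i, res_j = next_res, next_res + 2
        next_res += 4
        specs = _motif_atoms(motif.kind, res_i, res_j, origin)
        for name, element, resname, resnum, on_pos, off_pos in specs:
            names.append(name)
            elements.append(element)
            resnums.append(resnum)
            resnames.append(resname)
            atom_res_index.append(-1)  # motif atoms not given Gaussian noise
            motif_atom_specs.append((len(names) - 1, on_pos, off_pos))
        n_on = int(round(motif.fraction * n_frames))
        on_frames = rng.permutation(n_frames)[:n_on]
        motif_truth.append({
            "kind": motif.kind, "residues": (res_i, res_j),
            "fraction": motif.fraction, "n_on": n_on,
            "on_frames": sorted(int(f) for f in on_frames),
        })

    n_atoms = len(names)
    coords = np.zeros((n_frames, n_atoms, 3))
    for f in range(n_frames):
        disp = rng.normal(0.0, 1.0, (n_residues, 3)) * sigma[:, None]
        for a in range(n_atoms):
            ri = atom_res_index[a]
            if ri >= 0:
                coords[f, a] = base_coords[ri] + disp[ri]
    for t_idx, truth in enumerate(motif_truth):
        on_set = set(truth["on_frames"])
        for a_idx, on_pos, off_pos in motif_atom_specs:
            if resnums[a_idx] in truth["residues"]:
                for f in range(n_frames):
                    coords[f, a_idx] = on_pos if f in on_set else off_pos

    ens = Ensemble(
        coords=coords,
        atom_names=np.array(names),
        elements=np.array(elements),
        residue_numbers=np.array(resnums),
        residue_names=np.array(resnames),
        chains=np.array(["A"] * n_atoms),
    )
    truth = {
        "sigma": sigma.tolist(),
        "expected_rmsf": (sigma * np.sqrt(3.0)).tolist(),
        "motifs": motif_truth,
        "n_frames": n_frames,
        "seed": seed,
    }
    return ens, truth
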