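"""PDB structure handling for rigidity analysis.

Reading and writing go through biotite; the in-memory representation is a
flat list of :class:`AtomRecord` so the constraint-network code stays
independent of any particular structure library.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["AtomRecord", "parse_structure", "atoms_to_pdb", "apo_mimic", "coords_array"]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coords: tuple[float, float, float]
    is_hetero: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, float)


def coords_array(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([a.coords for a in atoms], float)


def parse_structure(pdb_text: str, keep_waters: bool = False) -> list[AtomRecord]:
    """Parse ATOM/HETATM records of a (single-model) PDB string.

    Alternate locations are resolved by highest occupancy ('A' on ties) and
    waters are dropped by default.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # malformed records -> informative rejection
        raise ValueError(f"could not parse PDB input: {exc}") from exc
    if not np.all(np.isfinite(arr.coord)):
        raise ValueError("non-finite coordinates in PDB input")

    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        if not keep_waters and res_name in _WATER_NAMES:
            continue
        serial += 1
        element = str(arr.element[i]).upper()
        atoms.append(
            AtomRecord(
                serial=serial,
                name=str(arr.atom_name[i]),
                element=element,
                residue_name=res_name,
                residue_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
                coords=tuple(round(float(c), 3) for c in arr.coord[i]),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    if not atoms:
        raise ValueError("no atoms found in PDB input")
    return atoms


def _to_atom_array(atoms: list[AtomRecord]) -> struc.AtomArray:
    arr = struc.AtomArray(len(atoms))
    arr.coord = coords_array(atoms)
    arr.atom_name = np.array([a.name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.res_id = np.array([a.residue_number for a in atoms])
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.hetero = np.array([a.is_hetero for a in atoms])
    return arr


def atoms_to_pdb(atoms: list[AtomRecord]) -> str:
    """Serialise atom records to PDB text (coordinates at PDB precision)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(atoms))
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def apo_mimic(atoms: list[AtomRecord], ligand_names: tuple[str, ...] = ("HEM",)) -> list[AtomRecord]:
    """Haem-stripped mimic: drop all atoms of the named hetero residues.

    Everything else (including renumbering) is untouched; a warning is
    emitted when no matching ligand is present (no-op).
    """
    kept = [a for a in atoms if a.residue_name not in ligand_names]
    if len(kept) == len(atoms):
        warnings.warn(f"no {'/'.join(ligand_names)} residue found; apo mimic is a no-op")
    return kept
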