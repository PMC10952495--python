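"""Constraint-network assembly, rigidity dilution and structural mimics.

The dilution progressively lowers the hydrogen-bond energy cutoff (default
−1.0 → −4.0 kcal/mol in 0.5 steps), excluding ever stronger hydrogen bonds
from the network, and records the residue membership of the largest rigid
cluster (RC1) at each cutoff. The glycosylation mimic adds artificial
Cα(i−1)–Cα(i)–Cα(i+1) bars at each glycosylated asparagine; the apo mimic
(haem removal) lives in :mod:`.structure`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bonds import (
    CovalentTopology,
    HydrogenBond,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
    infer_covalent_bonds,
)
from .pebble import Bar, ConstraintNetwork, RigidClusterDecomposition, pebble_game
from .structure import AtomRecord

__all__ = [
    "GlycosylationSpec",
    "DilutionProfile",
    "DEFAULT_CUTOFFS",
    "build_constraint_network",
    "glyco_mimic",
    "glyco_bars",
    "rigidity_dilution",
    "rc1_residues",
    "apply_energy_overrides",
]

log = logging.getLogger(__name__)

#: default hydrogen-bond energy cutoff grid for a dilution (kcal/mol)
DEFAULT_CUTOFFS = tuple(np.arange(-1.0, -4.01, -0.5))

#: bars per constraint type (body-bar conventions)
BARS_ROTATABLE = 5
BARS_LOCKED = 6
BARS_HBOND = 5
BARS_TETHER = 2


@dataclass(frozen=True)
class GlycosylationSpec:
    """Which asparagines carry a glycan and how strongly to rigidify them.

    Defaults are the eight N-linked sites of HRP. Each site contributes
    artificial bars Cα(i)–Cα(i−1) and Cα(i)–Cα(i+1); 6 bars fully lock the
    relative motion of the flanking Cα bodies.
    """

    asn_residues: tuple[int, ...] = (13, 57, 158, 186, 198, 214, 255, 268)
    bars_per_constraint: int = 6


def build_constraint_network(
    topology: CovalentTopology,
    hbonds: list[HydrogenBond],
    tethers: list[tuple[int, int]],
    cutoff: float,
    extra_bars: list[Bar] | None = None,
) -> ConstraintNetwork:
    """Assemble the body-bar network at one hydrogen-bond energy cutoff.

    Covalent bonds contribute 5 bars (rotatable) or 6 (locked); hydrogen
    bonds with energy ≤ cutoff contribute 5; hydrophobic tethers 2;
    artificial bars are appended verbatim. Deterministic given its inputs.
    """
    if cutoff > 0:
        raise ValueError("cutoff must be ≤ 0 kcal/mol")
    bars: list[Bar] = [
        Bar(i, j, BARS_ROTATABLE if rot else BARS_LOCKED, "covalent")
        for i, j, rot in topology.bonds
    ]
    bars += [
        Bar(hb.hydrogen, hb.acceptor, BARS_HBOND, "hbond", energy=hb.energy)
        for hb in hbonds
        if hb.energy <= cutoff
    ]
    bars += [Bar(i, j, BARS_TETHER, "tether") for i, j in tethers]
    if extra_bars:
        bars += list(extra_bars)
    return ConstraintNetwork(n_bodies=topology.n_atoms, bars=bars)


def glyco_bars(atoms: list[AtomRecord], spec: GlycosylationSpec) -> list[Bar]:
    """Artificial Cα–Cα bars for each glycosylation site in ``spec``.

    A site lacking a flanking residue (chain terminus) contributes only the
    constraint(s) that exist, with a log entry.
    """
    ca_index = {
        (a.chain, a.residue_number): i
        for i, a in enumerate(atoms)
        if a.name == "CA" and a.element == "C"
    }
    bars: list[Bar] = []
    for res in spec.asn_residues:
        site = [key for key in ca_index if key[1] == res]
        if not site:
            log.warning("glycosylation site %d has no Cα; skipped", res)
            continue
        for chain, num in site:
            i = ca_index[(chain, num)]
            for flank in (num - 1, num + 1):
                j = ca_index.get((chain, flank))
                if j is None:
                    log.warning("site %d lacks flanking residue %d; constraint skipped",
                                num, flank)
                    continue
                bars.append(Bar(i, j, spec.bars_per_constraint, "artificial"))
    return bars


def glyco_mimic(
    network: ConstraintNetwork, spec: GlycosylationSpec, atoms: list[AtomRecord]
) -> ConstraintNetwork:
    """Return a copy of ``network`` with the artificial glycan bars added."""
    return ConstraintNetwork(
        n_bodies=network.n_bodies, bars=list(network.bars) + glyco_bars(atoms, spec)
    )


def rc1_residues(
    decomposition: RigidClusterDecomposition, atoms: list[AtomRecord]
) -> set[tuple[str, int]]:
    """Residues whose Cα belongs to the largest rigid cluster (RC1).

    RC1 is the cluster with the most Cα members (ties broken by total atom
    count, then by cluster id); ranking by Cα membership makes the dilution
    profile provably non-increasing under partition refinement.
    """
    by_cluster: dict[int, set[tuple[str, int]]] = {}
    for i, a in enumerate(atoms):
        if a.name == "CA" and a.element == "C":
            cid = int(decomposition.cluster_id[i])
            by_cluster.setdefault(cid, set()).add((a.chain, a.residue_number))
    if not by_cluster:
        return set()
    sizes = decomposition.cluster_sizes()
    best = min(
        by_cluster, key=lambda c: (-len(by_cluster[c]), -int(sizes[c - 1]), c)
    )
    return by_cluster[best]


def apply_energy_overrides(
    hbonds: list[HydrogenBond],
    atoms: list[AtomRecord],
    table: dict[tuple[int, str, int, str], float],
) -> list[HydrogenBond]:
    """Replace detected H-bond energies with designed values.

    ``table`` maps (donor_resnum, donor_atom, acceptor_resnum, acceptor_atom)
    to an energy in kcal/mol; unmatched bonds keep their Mayo energy. Used by
    the synthetic structure generator so dilutions break at designed cutoffs.
    """
    out = []
    for hb in hbonds:
        d, a = atoms[hb.donor], atoms[hb.acceptor]
        key = (d.residue_number, d.name, a.residue_number, a.name)
        e = table.get(key, hb.energy)
        out.append(HydrogenBond(hb.donor, hb.hydrogen, hb.acceptor, e))
    return out


@dataclass
class DilutionProfile:
    """Per-cutoff RC1 sizes and the underlying decompositions."""

    cutoffs: tuple[float, ...]
    rc1_residue_counts: tuple[int, ...]
    decompositions: list[RigidClusterDecomposition] = field(repr=False, default_factory=list)
    rc1_residue_sets: list[set[tuple[str, int]]] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff_kcal_mol": self.cutoffs, "rc1_residue_count": self.rc1_residue_counts}
        )


def rigidity_dilution(
    atoms: list[AtomRecord],
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    glyco: GlycosylationSpec | None = None,
    include_tethers: bool = True,
    energy_overrides: dict | None = None,
) -> DilutionProfile:
    """Rigid-cluster decompositions over a decreasing cutoff grid.

    Bond, hydrogen-bond and tether detection run once; only the hydrogen-bond
    subset admitted by each cutoff changes along the dilution, so the RC1
    residue count is non-increasing toward more negative cutoffs.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(np.diff(cutoffs) >= 0):
        raise ValueError("cutoffs must be strictly decreasing")
    topology = infer_covalent_bonds(atoms)
    hbonds = detect_hydrogen_bonds(atoms, topology)
    if energy_overrides:
        hbonds = apply_energy_overrides(hbonds, atoms, energy_overrides)
    tethers = detect_hydrophobic_tethers(atoms, topology) if include_tethers else []
    extra = glyco_bars(atoms, glyco) if glyco is not None else None

    counts, decomps, residue_sets = [], [], []
    for cutoff in cutoffs:
        network = build_constraint_network(topology, hbonds, tethers, cutoff, extra)
        dec = pebble_game(network)
        members = rc1_residues(dec, atoms)
        counts.append(len(members))
        decomps.append(dec)
        residue_sets.append(members)
    return DilutionProfile(
        cutoffs=cutoffs,
        rc1_residue_counts=tuple(counts),
        decompositions=decomps,
        rc1_residue_sets=residue_sets,
    )
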