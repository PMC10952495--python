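"""Body-bar (6,6) pebble game and rigid-cluster decomposition.

Each body carries six pebbles (its six degrees of freedom). A bar between
bodies u and v is independent iff seven pebbles can be gathered onto {u, v};
inserting it consumes one pebble and directs an edge away from u. After all
bars are inserted, two bodies are mutually rigid iff no seventh pebble can
be gathered onto them — only the six trivial rigid-body motions remain.
Mutual rigidity is transitive, and generic rigid components induce connected
subgraphs, so rigid clusters are obtained by union-find over the bonded
pairs that test rigid.

The outcome (independent-bar count, redundancy, cluster partition) is a
property of the generic body-bar rigidity matroid and therefore independent
of insertion order; bars are nevertheless inserted in a canonical order so
that runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Bar", "ConstraintNetwork", "RigidClusterDecomposition", "pebble_game"]

DOF_PER_BODY = 6


@dataclass(frozen=True)
class Bar:
    """A multi-bar constraint between two bodies.

    ``count`` bars (1–6); ``origin`` tags the physical source
    (covalent | hbond | tether | artificial); hydrogen-bond bars carry their
    energy (kcal/mol) for dilution bookkeeping.
    """

    i: int
    j: int
    count: int
    origin: str = "covalent"
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-bars are not allowed")
        if not 1 <= self.count <= 6:
            raise ValueError("bar count must be in 1..6")


@dataclass
class ConstraintNetwork:
    """Bodies (6 DOF each) plus a multiset of bars between them."""

    n_bodies: int
    bars: list[Bar] = field(default_factory=list)

    def total_bar_count(self) -> int:
        return sum(b.count for b in self.bars)


class _PebbleGame:
    def __init__(self, n: int):
        self.n = n
        self.pebbles = [DOF_PER_BODY] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]
        self.independent = 0
        self.redundant = 0

    def _find_pebble(self, sources: tuple[int, ...]) -> bool:
        """DFS from the sources along directed edges for a free pebble not on
        a source; if found, move it back along the path (reversing edges)."""
        parent: dict[int, int] = {s: -1 for s in sources}
        stack = list(sources)
        found = -1
        while stack:
            u = stack.pop()
            for v in self.out[u]:
                if self.out[u][v] <= 0 or v in parent:
                    continue
                parent[v] = u
                if self.pebbles[v] > 0:
                    found = v
                    stack.clear()
                    break
                stack.append(v)
        if found < 0:
            return False
        # pull the pebble back to the originating source, reversing the path
        v = found
        self.pebbles[v] -= 1
        while parent[v] != -1:
            u = parent[v]
            self.out[u][v] -= 1
            if self.out[u][v] == 0:
                del self.out[u][v]
            self.out[v][u] = self.out[v].get(u, 0) + 1
            v = u
        self.pebbles[v] += 1
        return True

    def gather(self, u: int, v: int, target: int) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            if not self._find_pebble((u, v)):
                return False
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar copy; returns True if independent."""
        if not self.gather(u, v, DOF_PER_BODY + 1):
            self.redundant += 1
            return False
        # 7 pebbles on two bodies with <= 6 each: both have at least one
        if self.pebbles[u] == 0:
            u, v = v, u
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        self.independent += 1
        return True

    def mutually_rigid(self, u: int, v: int) -> bool:
        """After all insertions: True iff at most 6 pebbles can reach {u, v}."""
        return not self.gather(u, v, DOF_PER_BODY + 1)


@dataclass
class RigidClusterDecomposition:
    """Partition of the bodies into rigid clusters.

    ``cluster_id[b]`` numbers clusters from 1, ordered by decreasing size
    (ties by smallest member index); ``free_dof`` counts all remaining
    degrees of freedom including the six global rigid-body motions.
    """

    cluster_id: np.ndarray
    free_dof: int
    n_independent: int
    n_redundant: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) if self.cluster_id.size else 0

    def cluster_members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == cid)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_id)[1:]

    def largest_cluster(self) -> np.ndarray:
        """Members of RC1 (cluster id 1)."""
        return self.cluster_members(1)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pebble_game(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Run the (6,6) pebble game and return the rigid-cluster decomposition."""
    n = network.n_bodies
    game = _PebbleGame(n)

    canonical = sorted(
        network.bars,
        key=lambda b: (min(b.i, b.j), max(b.i, b.j), b.origin,
                       b.energy if b.energy is not None else 0.0),
    )
    for bar in canonical:
        u, v = min(bar.i, bar.j), max(bar.i, bar.j)
        if not (0 <= u < n and 0 <= v < n):
            raise ValueError("bar endpoint outside body range")
        for _ in range(bar.count):
            game.insert_bar(u, v)

    uf = _UnionFind(n)
    pairs = sorted({(min(b.i, b.j), max(b.i, b.j)) for b in network.bars})
    for u, v in pairs:
        if uf.find(u) != uf.find(v) and game.mutually_rigid(u, v):
            uf.union(u, v)

    roots: dict[int, list[int]] = {}
    for b in range(n):
        roots.setdefault(uf.find(b), []).append(b)
    ordered = sorted(roots.values(), key=lambda m: (-len(m), m[0]))
    cluster_id = np.zeros(n, dtype=int)
    for cid, members in enumerate(ordered, start=1):
        cluster_id[members] = cid

    return RigidClusterDecomposition(
        cluster_id=cluster_id,
        free_dof=sum(game.pebbles),
        n_independent=game.independent,
        n_redundant=game.redundant,
    )
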