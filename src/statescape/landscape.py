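"""Basins, barriers, and the disconnectivity dendrogram of an energy landscape.

The 2^n brain states form a hypercube graph: two states are neighbors when
they differ in exactly one region's activation.  A *basin* state is a local
energy minimum of that graph; every state is attributed to a basin by steepest
descent (repeatedly stepping to the lowest-energy neighbor), giving the basin's
cluster — its domain of attraction.  The *saddle* between two basins is the
minimax path energy: the lowest, over hypercube paths joining them, of the
highest energy met along the path.  The barrier out of basin a toward b is
saddle(a, b) - E(a), which is asymmetric when the basins have unequal depth.
Single-linkage agglomeration of basins on the saddle levels yields the
disconnectivity dendrogram.

All ties (degenerate energies) are broken by lower state code, so every
operation here is fully deterministic; ties have measure zero for models
fitted to real-valued data.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ising import EnergyTable


def _require_model_table(energies: EnergyTable) -> np.ndarray:
    if energies.kind != "model":
        raise ValueError(
            "landscape construction requires model energies (empirical energies "
            "are undefined for unobserved states)"
        )
    e = np.asarray(energies.energies, dtype=np.float64)
    if not np.isfinite(e).all():
        raise ValueError("energies must be finite")
    return e


def _neighbors(code: int, n: int) -> np.ndarray:
    return code ^ (1 << np.arange(n))


def find_basins(energies: EnergyTable) -> list[int]:
    """State codes that are local minima under single-flip neighborhoods.

    A state is a basin when its (energy, code) pair is lexicographically below
    every neighbor's — i.e. strictly lower energy, with lower state code as
    tie-break on exactly equal energies.  Under this rule a flat landscape has
    exactly one basin (code 0), and at least one basin always exists.
    """
    e = _require_model_table(energies)
    n = energies.n
    codes = np.arange(2**n, dtype=np.int64)
    is_basin = np.ones(2**n, dtype=bool)
    for i in range(n):
        nb = codes ^ (1 << i)
        worse = (e < e[nb]) | ((e == e[nb]) & (codes < nb))
        is_basin &= worse
    return [int(c) for c in np.flatnonzero(is_basin)]


@dataclass
class BasinPartition:
    """Assignment of every state to its steepest-descent basin.

    ``basin_codes`` are sorted by energy ascending (lower code first on ties);
    the first ``major`` holds the (up to) two lowest-energy basins — the pair
    whose clusters the transition-dynamics scores are defined on.
    """

    basin_codes: list[int]
    assignment: np.ndarray
    energies: np.ndarray  # per-basin energy, aligned with basin_codes
    n: int
    major: list[int] = field(default_factory=list)

    @property
    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.assignment, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    @property
    def fractions(self) -> dict[int, float]:
        total = len(self.assignment)
        return {b: c / total for b, c in self.sizes.items()}

    def cluster(self, basin_code: int) -> np.ndarray:
        """State codes attributed to the given basin."""
        return np.flatnonzero(self.assignment == basin_code)

    @property
    def minor(self) -> list[int]:
        return [b for b in self.basin_codes if b not in self.major]


def assign_to_basins(energies: EnergyTable) -> BasinPartition:
    """Steepest-descent attribution of every state to a basin.

    From each state, repeatedly move to the best single-flip neighbor (lowest
    energy, lowest code on ties) while that neighbor improves on the current
    state; the fixed point reached is the assigned basin.  Memoized over the
    descent paths, and guaranteed acyclic because the (energy, code) key
    strictly decreases at every move.
    """
    e = _require_model_table(energies)
    n = energies.n
    size = 2**n
    codes = np.arange(size, dtype=np.int64)

    # best neighbor of every state under the lexicographic (energy, code) key
    best_nb = np.zeros(size, dtype=np.int64)
    best_e = np.full(size, np.inf)
    for i in range(n):
        nb = codes ^ (1 << i)
        better = (e[nb] < best_e) | ((e[nb] == best_e) & (nb < best_nb))
        best_nb[better] = nb[better]
        best_e[better] = e[nb][better]

    improves = (best_e < e) | ((best_e == e) & (best_nb < codes))
    step = np.where(improves, best_nb, codes)

    # pointer-jumping: step is a functional graph whose cycles are fixed points
    assignment = step.copy()
    while True:
        nxt = assignment[assignment]
        if np.array_equal(nxt, assignment):
            break
        assignment = nxt

    basin_codes = sorted(
        (int(c) for c in np.unique(assignment)), key=lambda c: (e[c], c)
    )
    expected = set(find_basins(energies))
    assert set(basin_codes) == expected, "descent fixed points != local minima"
    part = BasinPartition(
        basin_codes=basin_codes,
        assignment=assignment,
        energies=e[np.asarray(basin_codes, dtype=np.int64)],
        n=n,
    )
    return classify_major_minor(part)


def classify_major_minor(partition: BasinPartition) -> BasinPartition:
    """Mark the two lowest-energy basins as major (all of them if fewer)."""
    k = min(2, len(partition.basin_codes))
    partition.major = list(partition.basin_codes[:k])
    return partition


@dataclass
class SaddleMatrix:
    """Minimax path energies between basins; barriers derive from them.

    ``saddle`` is symmetric with saddle(a, a) = E(a); the barrier out of a
    toward b is saddle(a, b) - E(a).
    """

    basin_codes: list[int]
    saddle: np.ndarray
    basin_energies: np.ndarray

    @property
    def barrier(self) -> np.ndarray:
        """barrier[i, j] = energy to leave basin i toward basin j (asymmetric)."""
        return self.saddle - self.basin_energies[:, None]

    def index(self, basin_code: int) -> int:
        return self.basin_codes.index(basin_code)


def saddle_energies(energies: EnergyTable, basins: Sequence[int]) -> SaddleMatrix:
    """Minimax ("widest-path") Dijkstra from each basin over the hypercube.

    A path's cost is the maximum state energy along it, endpoints included;
    Dijkstra with the relaxation new_cost = max(cost_so_far, E(neighbor))
    yields the optimum for this bottleneck objective.
    """
    e = _require_model_table(energies)
    n = energies.n
    basins = [int(b) for b in basins]
    m = len(basins)
    if m < 2:
        warnings.warn("single-basin landscape: no saddles to compute")
    saddle = np.zeros((m, m))
    for a_idx, a in enumerate(basins):
        cost = np.full(2**n, np.inf)
        cost[a] = e[a]
        heap = [(e[a], a)]
        while heap:
            c, u = heapq.heappop(heap)
            if c > cost[u]:
                continue
            for v in _neighbors(u, n):
                v = int(v)
                new_c = max(c, e[v])
                if new_c < cost[v]:
                    cost[v] = new_c
                    heapq.heappush(heap, (new_c, v))
        for b_idx, b in enumerate(basins):
            saddle[a_idx, b_idx] = cost[b]
    saddle = np.maximum(saddle, saddle.T)  # symmetric up to float identity anyway
    return SaddleMatrix(
        basin_codes=basins,
        saddle=saddle,
        basin_energies=e[np.asarray(basins, dtype=np.int64)],
    )


@dataclass
class DendrogramNode:
    """Node of the disconnectivity dendrogram.

    Leaves carry a basin code and its energy as ``merge_energy``; internal
    nodes carry two children and the saddle level at which their subtrees
    connect.  Merge energies are non-decreasing from leaves to root.
    """

    merge_energy: float
    basin_code: Optional[int] = None
    children: Optional[tuple["DendrogramNode", "DendrogramNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.basin_code]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self) -> str:
        """Newick string with branch length = parent merge level - child level."""

        def fmt(node: "DendrogramNode", parent_level: Optional[float]) -> str:
            if node.is_leaf:
                label = f"S{node.basin_code}"
            else:
                a, b = node.children
                label = f"({fmt(a, node.merge_energy)},{fmt(b, node.merge_energy)})"
            if parent_level is None:
                return label
            return f"{label}:{parent_level - node.merge_energy:.6g}"

        return fmt(self, None) + ";"

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"basin": self.basin_code, "energy": self.merge_energy}
        return {
            "merge_energy": self.merge_energy,
            "children": [c.to_dict() for c in self.children],
        }


def build_dendrogram(saddles: SaddleMatrix) -> DendrogramNode:
    """Single-linkage agglomeration of basins on saddle levels.

    Repeatedly merge the two clusters with the smallest cross-pair saddle at
    that level.  The saddle matrix satisfies the ultrametric-like inequality
    saddle(a, c) <= max(saddle(a, b), saddle(b, c)), so the min cross-pair
    saddle is the true connection level of the merged clusters.
    """
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(merge_energy=float(saddles.basin_energies[i]), basin_code=c)
        for i, c in enumerate(saddles.basin_codes)
    }
    members: dict[int, list[int]] = {i: [i] for i in nodes}
    while len(nodes) > 1:
        best = None
        for a in sorted(nodes):
            for b in sorted(nodes):
                if b <= a:
                    continue
                s = min(saddles.saddle[i, j] for i in members[a] for j in members[b])
                if best is None or s < best[0]:
                    best = (s, a, b)
        s, a, b = best
        new_id = max(nodes) + 1
        nodes[new_id] = DendrogramNode(
            merge_energy=float(s), children=(nodes.pop(a), nodes.pop(b))
        )
        members[new_id] = members.pop(a) + members.pop(b)
    return nodes.popitem()[1]


def landscape_profile(
    energies: EnergyTable, partition: BasinPartition, basin: int
) -> list[tuple[int, float]]:
    """Radial depth profile of one basin's cluster (concentric-circle view).

    For each Hamming radius r occurring within the cluster, the depth is the
    minimum energy among cluster states at distance r from the basin state;
    r = 0 is the basin's own energy.
    """
    if basin not in partition.basin_codes:
        raise ValueError(f"{basin} is not a basin of this partition")
    e = _require_model_table(energies)
    cluster = partition.cluster(basin)
    dist = np.array([bin(int(c) ^ basin).count("1") for c in cluster])
    profile = []
    for r in range(int(dist.max()) + 1):
        at_r = cluster[dist == r]
        if len(at_r):
            profile.append((r, float(e[at_r].min())))
    return profile
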