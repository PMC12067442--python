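"""Generation of saturated mono- and bicyclic carbon ring systems.

The enumeration universe is every connected all-carbon ring system with
circuit rank 1 or 2 whose smallest-set-of-smallest-rings (SSSR) sizes all
lie in a configured size set (default {5, 6, 7}). Bicyclic systems fall
into three topologies by how the two rings share atoms:

* **spiro** — one shared atom (the spiro center, four ring bonds);
* **fused** — one shared edge (two adjacent bridgehead atoms);
* **bridged** — two non-adjacent bridgeheads joined by three bridges.

Fused and bridged systems are parameterized in von Baeyer style as
bicyclo[x.y.z]alkanes: two bridgeheads joined by three paths carrying
x >= y >= z interior atoms (z = 0 is the fused case). The two SSSR rings
then have sizes y+z+2 and x+z+2. Ring systems are derived analytically
from this parameterization; for sizes {5,6,7} this yields the complete
set of 24 frameworks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx

from .graphs import MolecularGraph, canonical_key


class RingType(enum.Enum):
    MONOCYCLIC = "monocyclic"
    SPIROCYCLIC = "spirocyclic"
    FUSED = "fused"
    BRIDGED = "bridged"


_TYPE_RANK = {
    RingType.MONOCYCLIC: 0,
    RingType.SPIROCYCLIC: 1,
    RingType.FUSED: 2,
    RingType.BRIDGED: 3,
}

_ALKANE = {
    3: "propane", 4: "butane", 5: "pentane", 6: "hexane", 7: "heptane",
    8: "octane", 9: "nonane", 10: "decane", 11: "undecane",
    12: "dodecane", 13: "tridecane", 14: "tetradecane",
}


class RingSizeError(ValueError):
    """Raised for ring sizes below 3 (no such carbocycle exists)."""


class MalformedSkeletonError(ValueError):
    """Raised when a graph matches no mono-/bicyclic topology signature."""


@dataclass(frozen=True)
class BridgeSpec:
    """Bridge atom counts (x, y, z), x >= y >= z >= 0, of a bicyclo[x.y.z] core.

    z = 0 means the bridgeheads are directly bonded (a fused system);
    z >= 1 gives a bridged system.
    """

    x: int
    y: int
    z: int

    def __post_init__(self):
        if not (self.x >= self.y >= self.z >= 0):
            raise ValueError(f"bridge lengths must satisfy x>=y>=z>=0: {self}")

    @property
    def ring_sizes(self) -> tuple[int, int]:
        return tuple(sorted((self.y + self.z + 2, self.x + self.z + 2)))

    def build_graph(self) -> MolecularGraph:
        """Two bridgehead atoms (0, 1) joined by three carbon paths."""
        n = 2 + self.x + self.y + self.z
        bonds = set()
        nxt = 2
        for length in (self.x, self.y, self.z):
            if length == 0:
                bonds.add((0, 1))
                continue
            prev = 0
            for _ in range(length):
                bonds.add((prev, nxt))
                prev = nxt
                nxt += 1
            bonds.add((prev, 1))
        return MolecularGraph(["C"] * n, bonds)


@dataclass(frozen=True)
class CarbonSkeleton:
    """All-carbon ring system: the substrate every scaffold is built on."""

    graph: MolecularGraph
    ring_type: RingType
    ring_sizes: tuple[int, ...]
    name: str

    @property
    def key(self) -> str:
        return canonical_key(self.graph)


def _check_sizes(sizes) -> list[int]:
    sizes = sorted(set(sizes))
    for s in sizes:
        if s < 3:
            raise RingSizeError(f"ring size {s} < 3 is impossible")
    return sizes


def _pairs(sizes) -> list[tuple[int, int]]:
    """Unordered size pairs with repetition, sorted."""
    sizes = _check_sizes(sizes)
    return [
        (a, b) for i, a in enumerate(sizes) for b in sizes[i:]
    ]


def classify_ring_type(graph: MolecularGraph) -> RingType:
    """Topology class from the branch-vertex signature of a ring system.

    Circuit rank 1 is monocyclic. At rank 2 the shared atoms show up as
    degree anomalies: one degree-4 atom (spiro), or two degree-3 atoms
    that are adjacent (fused) or not (bridged).
    """
    graph.validate()
    rank = graph.circuit_rank
    degs = [graph.degree(i) for i in range(graph.n_atoms)]
    if rank == 1:
        if all(d == 2 for d in degs):
            return RingType.MONOCYCLIC
        raise MalformedSkeletonError("monocyclic graph with branch atoms")
    if rank != 2:
        raise MalformedSkeletonError(f"circuit rank {rank}, expected 1 or 2")
    deg4 = [i for i, d in enumerate(degs) if d == 4]
    deg3 = [i for i, d in enumerate(degs) if d == 3]
    if len(deg4) == 1 and not deg3:
        return RingType.SPIROCYCLIC
    if len(deg3) == 2 and not deg4:
        i, j = deg3
        bond = (i, j) if i < j else (j, i)
        return RingType.FUSED if bond in graph.bonds else RingType.BRIDGED
    raise MalformedSkeletonError(
        f"degree signature deg3={deg3}, deg4={deg4} matches no bicyclic type"
    )


def sssr_sizes(graph: MolecularGraph) -> tuple[int, ...]:
    """Sorted SSSR ring sizes via a minimum cycle basis of the graph."""
    basis = nx.minimum_cycle_basis(graph.to_networkx())
    return tuple(sorted(len(c) for c in basis))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_monocycles(sizes) -> list[CarbonSkeleton]:
    """One cycloalkane ring per requested size, ascending."""
    out = []
    for n in _check_sizes(sizes):
        bonds = {(i, (i + 1) % n) for i in range(n)}
        out.append(
            CarbonSkeleton(
                graph=MolecularGraph(["C"] * n, bonds),
                ring_type=RingType.MONOCYCLIC,
                ring_sizes=(n,),
                name=f"cyclo{_ALKANE[n]}",
            )
        )
    return out


def generate_spiro(size_pairs) -> list[CarbonSkeleton]:
    """One spiro skeleton per unordered size pair: two rings sharing one atom."""
    out = []
    for a, b in sorted(tuple(sorted(p)) for p in set(size_pairs)):
        _check_sizes([a, b])
        # atom 0 is the spiro center; ring A uses 1..a-1, ring B uses a..a+b-2
        bonds = set()
        ring_a = [0] + list(range(1, a))
        ring_b = [0] + list(range(a, a + b - 1))
        for ring in (ring_a, ring_b):
            for i in range(len(ring)):
                bonds.add((ring[i], ring[(i + 1) % len(ring)]))
        out.append(
            CarbonSkeleton(
                graph=MolecularGraph(["C"] * (a + b - 1), bonds),
                ring_type=RingType.SPIROCYCLIC,
                ring_sizes=(a, b),
                name=f"spiro[{a - 1}.{b - 1}]{_ALKANE[a + b - 1]}",
            )
        )
    return out


def generate_fused(size_pairs) -> list[CarbonSkeleton]:
    """One fused skeleton per unordered size pair: two rings sharing one edge."""
    out = []
    for a, b in sorted(tuple(sorted(p)) for p in set(size_pairs)):
        _check_sizes([a, b])
        spec = BridgeSpec(b - 2, a - 2, 0)
        out.append(
            CarbonSkeleton(
                graph=spec.build_graph(),
                ring_type=RingType.FUSED,
                ring_sizes=(a, b),
                name=f"bicyclo[{spec.x}.{spec.y}.0]{_ALKANE[a + b - 2]}",
            )
        )
    return out


def generate_bridged(size_pairs) -> list[CarbonSkeleton]:
    """All bridged bicyclo[x.y.z] skeletons (z >= 1) with the requested SSSR pairs.

    For each unordered pair every (x, y, z) with x >= y >= z >= 1 whose two
    smallest rings (sizes y+z+2 and x+z+2) match the pair is emitted;
    distinct bridge specs give non-isomorphic graphs, which is asserted via
    canonical-key deduplication.
    """
    wanted = {tuple(sorted(p)) for p in size_pairs}
    for a, b in wanted:
        _check_sizes([a, b])
    max_size = max((p[1] for p in wanted), default=0)
    out, seen = [], set()
    for pair in sorted(wanted):
        for x in range(1, max_size):
            for y in range(1, x + 1):
                for z in range(1, y + 1):
                    spec = BridgeSpec(x, y, z)
                    if spec.ring_sizes != pair:
                        continue
                    skel = CarbonSkeleton(
                        graph=spec.build_graph(),
                        ring_type=RingType.BRIDGED,
                        ring_sizes=pair,
                        name=(
                            f"bicyclo[{x}.{y}.{z}]"
                            f"{_ALKANE[2 + x + y + z]}"
                        ),
                    )
                    k = skel.key
                    if k not in seen:
                        seen.add(k)
                        out.append(skel)
    return out


def generate_all(sizes) -> list[CarbonSkeleton]:
    """The complete mono- and bicyclic ring-system set for a size set.

    Concatenates the four generators, deduplicates globally by canonical
    key, and sorts by (ring-type rank, ring sizes, name) so that repeated
    runs give identical output. For sizes {5, 6, 7} this produces the full
    24-framework universe (3 monocyclic, 6 spiro, 6 fused, 9 bridged).
    """
    sizes = _check_sizes(sizes)
    if not sizes:
        raise RingSizeError("size set must be non-empty")
    pairs = _pairs(sizes)
    skeletons = (
        generate_monocycles(sizes)
        + generate_spiro(pairs)
        + generate_fused(pairs)
        + generate_bridged(pairs)
    )
    seen, out = set(), []
    for s in skeletons:
        k = s.key
        if k not in seen:
            seen.add(k)
            out.append(s)
    out.sort(key=lambda s: (_TYPE_RANK[s.ring_type], s.ring_sizes, s.name))
    return out


def write_skeletons(skeletons, path) -> None:
    """SMILES export: one line per skeleton, tab-separated metadata."""
    from .graphs import to_smiles

    with open(path, "w", encoding="utf-8") as fh:
        for s in skeletons:
            sizes = ",".join(str(x) for x in s.ring_sizes)
            fh.write(
                f"{to_smiles(s.graph)}\t{s.name}\t{s.ring_type.value}\t{sizes}\n"
            )
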