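"""Molecular graphs for saturated C/N compounds with implicit hydrogens.

The whole enumerated chemical space lives on one substrate: a connected
simple graph whose vertices are heavy atoms (carbon or nitrogen), whose
edges are single bonds, and whose hydrogens are implicit — each atom
carries ``valence(element) - heavy_degree`` hydrogens (valence 4 for C,
3 for N). No charges, no stereochemistry, no isotopes.

Graph identity is 2D constitutional identity: two graphs are the same
compound iff they are isomorphic as element-labeled graphs.
:func:`canonical_key` provides a relabeling-invariant string realizing
that identity, used everywhere for deduplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

VALENCE = {"C": 4, "N": 3}

#: IUPAC standard (average) atomic weights, Da, to 3 decimals.
ATOMIC_WEIGHT = {"C": 12.011, "H": 1.008, "N": 14.007}


class GraphValidationError(ValueError):
    """Raised when a molecular graph violates connectivity or valence rules."""


def _norm_bond(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise GraphValidationError(f"self-bond on atom {i}")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph over {C, N} with all-single bonds and implicit H.

    Parameters
    ----------
    elements
        Element symbol per atom index.
    bonds
        Unordered atom-index pairs; stored normalized as (lo, hi).
    """

    elements: tuple[str, ...]
    bonds: frozenset[tuple[int, int]]

    def __init__(self, elements, bonds):
        object.__setattr__(self, "elements", tuple(elements))
        object.__setattr__(
            self, "bonds", frozenset(_norm_bond(i, j) for i, j in bonds)
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in b)

    def implicit_h(self, i: int) -> int:
        return VALENCE[self.elements[i]] - self.degree(i)

    @property
    def circuit_rank(self) -> int:
        return len(self.bonds) - self.n_atoms + 1

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`GraphValidationError` unless the graph is well formed."""
        if self.n_atoms == 0:
            raise GraphValidationError("empty graph")
        bad = set(self.elements) - set(VALENCE)
        if bad:
            raise GraphValidationError(f"unsupported elements: {sorted(bad)}")
        for i, j in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise GraphValidationError(f"bond ({i},{j}) out of range")
        for i in range(self.n_atoms):
            if self.implicit_h(i) < 0:
                raise GraphValidationError(
                    f"atom {i} ({self.elements[i]}) exceeds valence "
                    f"{VALENCE[self.elements[i]]}"
                )
        if not nx.is_connected(self.to_networkx()):
            raise GraphValidationError("graph is not connected")

    # -- derived graphs ----------------------------------------------------

    def with_elements(self, replacements: dict[int, str]) -> "MolecularGraph":
        """Copy with element symbols substituted at the given indices."""
        elems = list(self.elements)
        for i, sym in replacements.items():
            elems[i] = sym
        return MolecularGraph(elems, self.bonds)

    def with_pendant(self, site: int, element: str) -> "MolecularGraph":
        """Copy with a new terminal atom bonded to ``site``."""
        new = self.n_atoms
        return MolecularGraph(
            list(self.elements) + [element], set(self.bonds) | {(site, new)}
        )

    def relabel(self, perm: list[int]) -> "MolecularGraph":
        """Apply permutation ``perm`` (new index of atom i is perm[i])."""
        elems = [""] * self.n_atoms
        for i, sym in enumerate(self.elements):
            elems[perm[i]] = sym
        return MolecularGraph(
            elems, {(perm[i], perm[j]) for i, j in self.bonds}
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, sym in enumerate(self.elements):
            g.add_node(i, element=sym)
        g.add_edges_from(self.bonds)
        return g

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.RWMol()
        for sym in self.elements:
            mol.AddAtom(Chem.Atom(sym))
        for i, j in self.bonds:
            mol.AddBond(i, j, Chem.BondType.SINGLE)
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out


# ---------------------------------------------------------------------------
# canonical key / formula / SMILES
# ---------------------------------------------------------------------------


def canonical_key(g: MolecularGraph) -> str:
    """Relabeling-invariant identifier of ``g`` up to graph isomorphism.

    Realized as the RDKit canonical SMILES of the molecule; two graphs get
    equal keys iff they are isomorphic as element-labeled simple graphs
    (single bonds, no charges or stereo).
    """
    g.validate()
    return Chem.MolToSmiles(g.to_rdkit())


def to_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of ``g`` (no stereo descriptors, no charges)."""
    return canonical_key(g)


def from_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Only saturated, uncharged C/N molecules are accepted — anything with
    other elements, ring aromaticity, multiple bonds, or formal charge is
    outside the modeled space and raises :class:`GraphValidationError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphValidationError(f"unparseable SMILES: {smiles!r}")
    elems = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in VALENCE:
            raise GraphValidationError(
                f"unsupported element {atom.GetSymbol()} in {smiles!r}"
            )
        if atom.GetFormalCharge() != 0:
            raise GraphValidationError(f"charged atom in {smiles!r}")
        if atom.GetIsAromatic():
            raise GraphValidationError(f"aromatic atom in {smiles!r}")
        elems.append(atom.GetSymbol())
    bonds = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            raise GraphValidationError(f"non-single bond in {smiles!r}")
        bonds.add((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    g = MolecularGraph(elems, bonds)
    g.validate()
    return g


@dataclass(frozen=True)
class Formula:
    """Molecular formula (C, H, N counts) and average molecular weight in Da."""

    c: int
    h: int
    n: int
    weight: float = field(compare=False)

    def __str__(self) -> str:
        parts = []
        if self.c:
            parts.append(f"C{self.c if self.c > 1 else ''}")
        if self.h:
            parts.append(f"H{self.h if self.h > 1 else ''}")
        if self.n:
            parts.append(f"N{self.n if self.n > 1 else ''}")
        return "".join(parts)


def formula(g: MolecularGraph) -> Formula:
    """Element counts with implicit hydrogens, and the average-weight MW."""
    g.validate()
    c = sum(1 for e in g.elements if e == "C")
    n = sum(1 for e in g.elements if e == "N")
    h = sum(g.implicit_h(i) for i in range(g.n_atoms))
    weight = (
        c * ATOMIC_WEIGHT["C"] + h * ATOMIC_WEIGHT["H"] + n * ATOMIC_WEIGHT["N"]
    )
    return Formula(c=c, h=h, n=n, weight=weight)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "piperazine": "C1CNCCN1",
    "pyrrolidine": "C1CCNC1",
    "piperidine": "C1CCNCC1",
    "cyclohexylamine": "NC1CCCCC1",
    "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1",
    "norbornane": "C1CC2CCC1C2",
    "decalin": "C1CCC2CCCCC2C1",
    "hydrindane": "C1CCC2CCCC2C1",
    "bicyclo[2.2.2]octane": "C1CC2CCC1CC2",
    "dabco": "C1CN2CCN1CC2",
}


def fixture_molecule(name: str) -> MolecularGraph:
    """Return a named reference molecule from the fixture registry.

    Available names: piperazine, pyrrolidine, piperidine, cyclohexylamine,
    cyclopentane, cyclohexane, norbornane, decalin, hydrindane,
    bicyclo[2.2.2]octane, dabco.
    """
    try:
        return from_smiles(_FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


# ---------------------------------------------------------------------------
# brute-force isomorphism oracle (testing aid; independent of RDKit)
# ---------------------------------------------------------------------------


def isomorphic_by_permutation(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Exhaustive-permutation isomorphism check.

    Feasible only for small graphs (<= 9 heavy atoms). Intended as an
    independent cross-check of :func:`canonical_key`, so it deliberately
    avoids any canonicalization machinery.
    """
    if a.n_atoms != b.n_atoms or sorted(a.elements) != sorted(b.elements):
        return False
    if len(a.bonds) != len(b.bonds):
        return False
    n = a.n_atoms
    for perm in itertools.permutations(range(n)):
        if any(a.elements[i] != b.elements[perm[i]] for i in range(n)):
            continue
        if all((_norm_bond(perm[i], perm[j])) in b.bonds for i, j in a.bonds):
            return True
    return False
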