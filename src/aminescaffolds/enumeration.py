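"""Nitrogen-feature enumeration over carbon ring systems.

Each scaffold is a carbon skeleton carrying one or two nitrogen features,
applied as a simultaneous set:

* ``RING_N`` — a ring carbon exchanged for nitrogen (C -> N);
* ``EXO_NH2`` — a primary amine appended to a ring carbon (C-H -> C-NH2).

Three chemical-validity rules prune the raw combinatorial space:

* **hydrazine** — no N-N bond;
* **aminal** — no carbon with two nitrogen neighbors (covers ring N-C-N,
  ring-N next to an aminomethine carbon, and geminal diamines uniformly);
* **quaternary** — no nitrogen with four heavy-atom neighbors (would arise
  only from substituting a spiro center).

Survivors are deduplicated up to graph symmetry by canonical key, so each
scaffold is counted once per automorphism orbit of feature placements.
Nitrogens are classified by heavy-degree into tertiary (N), secondary (NH)
and primary (NH2) amines; a scaffold's profile is the multiset of its
amine classes.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

from .graphs import Formula, MolecularGraph, canonical_key, formula
from .skeletons import CarbonSkeleton


class FeatureKind(enum.Enum):
    RING_N = "ring_n"
    EXO_NH2 = "exo_nh2"


@dataclass(frozen=True)
class NitrogenFeature:
    kind: FeatureKind
    site: int


class AmineClass(enum.Enum):
    """Amine substitution class of a nitrogen, by heavy-atom degree."""

    N = "N"      # tertiary: 3 heavy neighbors
    NH = "NH"    # secondary: 2 heavy neighbors
    NH2 = "NH2"  # primary: 1 heavy neighbor


_CLASS_ORDER = {AmineClass.N: 0, AmineClass.NH: 1, AmineClass.NH2: 2}

#: The nine amine-type profile columns, in canonical order.
COLUMN_KEYS = (
    "N", "NH", "NH2", "N/N", "N/NH", "N/NH2", "NH/NH", "NH/NH2", "NH2/NH2",
)


def amine_class(g: MolecularGraph, n_index: int) -> AmineClass:
    """Classify the nitrogen at ``n_index`` by its heavy-atom degree."""
    if g.elements[n_index] != "N":
        raise TypeError(f"atom {n_index} is {g.elements[n_index]}, not N")
    deg = g.degree(n_index)
    return {3: AmineClass.N, 2: AmineClass.NH, 1: AmineClass.NH2}[deg]


def profile_key(classes) -> str:
    """Render a multiset of amine classes as a profile column key (N < NH < NH2)."""
    ordered = sorted(classes, key=_CLASS_ORDER.__getitem__)
    return "/".join(c.value for c in ordered)


@dataclass(frozen=True)
class Violation:
    rule: str
    atoms: tuple[int, ...]


def is_valid(g: MolecularGraph) -> tuple[bool, Violation | None]:
    """Check the hydrazine / aminal / quaternary exclusion rules.

    Returns (True, None) or (False, first violation found). Rule order:
    hydrazine, aminal, quaternary.
    """
    for i, j in sorted(g.bonds):
        if g.elements[i] == "N" and g.elements[j] == "N":
            return False, Violation("hydrazine", (i, j))
    for i in range(g.n_atoms):
        if g.elements[i] != "C":
            continue
        n_nbrs = [j for j in g.neighbors(i) if g.elements[j] == "N"]
        if len(n_nbrs) >= 2:
            return False, Violation("aminal", (i, *n_nbrs))
    for i in range(g.n_atoms):
        if g.elements[i] == "N" and g.degree(i) >= 4:
            return False, Violation("quaternary", (i,))
    return True, None


@dataclass(frozen=True)
class Scaffold:
    """A ring system decorated with 1-2 nitrogen features, with identity data."""

    parent: CarbonSkeleton
    features: tuple[NitrogenFeature, ...]
    graph: MolecularGraph
    key: str
    profile: str
    formula: Formula


def _apply_features(
    skeleton: MolecularGraph, features
) -> MolecularGraph:
    ring_n = {f.site: "N" for f in features if f.kind is FeatureKind.RING_N}
    g = skeleton.with_elements(ring_n)
    for f in features:
        if f.kind is FeatureKind.EXO_NH2:
            g = g.with_pendant(f.site, "N")
    return g


def feature_candidates(skeleton: CarbonSkeleton, k: int):
    """All labeled size-``k`` feature sets satisfying per-feature site rules.

    RING_N may target any ring atom with at most 3 ring bonds (a degree-4
    spiro center would become quaternary nitrogen); EXO_NH2 any ring carbon
    retaining an implicit hydrogen, bridgeheads included. Combinations
    placing two features on one site are suppressed: RING_N + anything on
    the same atom is contradictory, and geminal double NH2 both breaches
    carbon valence at branch atoms and is an aminal regardless.
    """
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    g = skeleton.graph
    singles = []
    for i in range(g.n_atoms):
        if g.degree(i) <= 3:
            singles.append(NitrogenFeature(FeatureKind.RING_N, i))
        if g.implicit_h(i) >= 1:
            singles.append(NitrogenFeature(FeatureKind.EXO_NH2, i))
    if k == 1:
        return [(f,) for f in singles]
    return [
        (a, b)
        for a, b in itertools.combinations(singles, 2)
        if a.site != b.site
    ]


def enumerate_scaffolds(skeleton: CarbonSkeleton) -> list[Scaffold]:
    """All unique valid 1- and 2-feature scaffolds on one skeleton.

    Every candidate feature set is applied, invalid products are filtered
    by :func:`is_valid`, and survivors are deduplicated by canonical key
    (symmetry-equivalent placements collapse to one scaffold). Output is
    sorted by key.
    """
    seen: dict[str, Scaffold] = {}
    for k in (1, 2):
        for feats in feature_candidates(skeleton, k):
            g = _apply_features(skeleton.graph, feats)
            ok, _ = is_valid(g)
            if not ok:
                continue
            key = canonical_key(g)
            if key in seen:
                continue
            classes = [
                amine_class(g, i)
                for i in range(g.n_atoms)
                if g.elements[i] == "N"
            ]
            seen[key] = Scaffold(
                parent=skeleton,
                features=feats,
                graph=g,
                key=key,
                profile=profile_key(classes),
                formula=formula(g),
            )
    return [seen[k] for k in sorted(seen)]


def enumerate_all(skeletons) -> list[Scaffold]:
    """Union of per-skeleton enumerations, globally deduplicated by key."""
    skeletons = list(skeletons)
    if not skeletons:
        raise ValueError("skeleton list must be non-empty")
    seen: dict[str, Scaffold] = {}
    for skel in skeletons:
        for sc in enumerate_scaffolds(skel):
            if sc.key not in seen:
                seen[sc.key] = sc
    return [seen[k] for k in sorted(seen)]


def write_scaffolds(scaffolds, path) -> None:
    """Tab-separated SMILES export of a scaffold set.

    Columns: canonical SMILES, parent name, ring type, ring sizes,
    amine-type profile, formula, MW (2 decimals).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sc in scaffolds:
            sizes = ",".join(str(x) for x in sc.parent.ring_sizes)
            fh.write(
                f"{sc.key}\t{sc.parent.name}\t{sc.parent.ring_type.value}\t"
                f"{sizes}\t{sc.profile}\t{sc.formula}\t"
                f"{sc.formula.weight:.2f}\n"
            )
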