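# Methods

## The enumerated space

The package enumerates every constitutional isomer obtainable by placing
one or two nitrogen features on a saturated mono- or bicyclic carbon
ring system. The model is deliberately austere:

* heavy atoms are C and N only, all bonds single, no charges, isotopes
  or stereochemistry (identity is 2D graph identity);
* hydrogens are implicit: each atom carries `valence − heavy-degree`
  hydrogens, with valence 4 for carbon and 3 for nitrogen;
* ring systems have circuit rank 1 or 2 and all SSSR ring sizes in a
  configured set (default {5, 6, 7}); there are no acyclic appendages
  other than the NH₂ feature itself.

Stereoisomer expansion (cis/trans fusion, R/S centres) is out of scope
by design: counts are per constitution.

## Ring-system generation

Rather than consuming an external framework database, ring systems are
derived from a closed parameterization, which makes the generator the
pipeline's self-contained data source:

* **monocycles** — one cycle graph per size;
* **spiro** — two cycles sharing one atom, one skeleton per unordered
  size pair;
* **fused / bridged** — von Baeyer bicyclo[x.y.z] graphs: two
  bridgeheads joined by three paths with x ≥ y ≥ z ≥ 0 interior atoms
  (z = 0 fused, z ≥ 1 bridged). The two SSSR rings have sizes y+z+2 and
  x+z+2; for the bridged case all (x, y, z) matching a requested size
  pair are emitted.

At circuit rank 2 these four constructions are exhaustive — any bicyclic
graph has either one degree-4 ring atom (spiro) or two degree-3
bridgeheads joined by three bridges — so completeness needs no search
beyond the closed form. For sizes {5, 6, 7} the generator yields 24
frameworks (3/6/6/9 across mono/spiro/fused/bridged); this partition is
asserted in tests rather than assumed.

`classify_ring_type` recomputes topology from the degree signature and
must agree with the constructor's label for every generated skeleton;
`sssr_sizes` uses a minimum cycle basis (networkx) and is tested against
both the bicyclo closed form and exhaustive simple-cycle listing.

## Feature enumeration and validity rules

Features are applied as a simultaneous set — ring C → N substitutions
and exocyclic C–NH₂ attachments — with at most two per scaffold (fixed
by contract, not configurable). Site rules: ring C → N requires ring
degree ≤ 3 (a spiro centre would give quaternary N); C–NH₂ requires an
available implicit hydrogen, which bridgehead CH atoms do have. Two
features never share a site: ring-N plus anything on the same atom is
contradictory, and geminal double NH₂ both breaches carbon valence at
branch atoms and would be an aminal regardless, so such pairs are
suppressed at candidate generation.

The three validity rules are applied to the decorated graph:

1. **hydrazine** — no N–N bond (only two adjacent ring substitutions
   can produce one, since NH₂ attaches to carbon by construction);
2. **aminal** — no carbon with ≥ 2 nitrogen neighbours, one rule
   uniformly covering ring N–C–N, ring N adjacent to an NH₂-bearing
   carbon, and geminal diamines;
3. **quaternary** — no nitrogen with ≥ 4 heavy neighbours.

Violation reports name the first broken rule and the offending atoms
(checked in rule order: hydrazine, aminal, quaternary).

Survivors are deduplicated by canonical key per skeleton and then
globally; the global pass is asserted to be a no-op (distinct ring
frameworks cannot produce isomorphic scaffolds), not assumed.

## Canonicalization

Canonical keys delegate to RDKit's canonical SMILES. The contract —
equal keys iff element-labelled graph isomorphism, on graphs of ≤ 16
heavy atoms — is what the tests pin down, using two independent oracles:
exhaustive-permutation isomorphism on small scaffolds and VF2
automorphism search for symmetry-orbit counts. The orbit check is the
sharpest one: for every skeleton, the number of unique single-ring-N
scaffolds must equal the number of automorphism orbits of valid sites.

## Tabulation and statistics

Each scaffold increments exactly one ring-size row (the parent
skeleton's SSSR sizes — unchanged by substitution or NH₂ attachment) and
one ring-type row, against its amine-profile column (multiset of N/NH/NH₂
classes assigned by nitrogen heavy-degree). Totals are always derived,
never stored, so cross-footing (size block = type block = total row) is
structural.

Molecular weight uses IUPAC standard average atomic weights to three
decimals (C 12.011, H 1.008, N 14.007). The reported spread is the
population standard deviation; at n ≈ 10³ the sample/population
difference (< 0.02 Da) is far below reporting precision. Statistics are
computed over the unique (post-deduplication) scaffold set.

Novelty annotation is a pure offline join against a user-supplied
reference list of SMILES or canonical keys; the package ships no
database knowledge and never queries one. Unparseable reference entries
are skipped and counted.

## Determinism and numerical choices

There is no randomness anywhere in the pipeline: skeleton order is
(type rank, ring sizes, name), scaffold order is sorted canonical key,
and two runs produce byte-identical SMILES/CSV/JSON outputs (tested).
Degenerate inputs are defined: an empty scaffold set yields an all-zero
table, and summary statistics on an empty set raise rather than return
NaN.

## Limitations

* Only C/N saturated chemistry; O/S heteroatoms, unsaturation,
  aromaticity, charges and stereochemistry are out of scope.
* Ring sizes outside 3–9 and circuit rank ≥ 3 (tricyclics) are not
  generated; sizes other than {5, 6, 7} are accepted but correspond to a
  different universe than the tabulated one.
* The feature count is capped at two; the scaffold counts say nothing
  about tri-amine spaces.
* Counts are constitutional: a scaffold that exists only as strained
  stereoisomers is still counted once, since synthesizability is not
  modelled.
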