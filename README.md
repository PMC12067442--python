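# aminescaffolds

Exhaustive enumeration of the chemical space of saturated mono- and
bicyclic amine and diamine ring scaffolds — the small, sp³-rich ring
frameworks (pyrrolidines, piperidines, azepanes, aza-spiro, aza-fused and
aza-bridged bicyclics) that medicinal chemists use as building blocks.
The package answers a simple question completely: *how many distinct
amine/diamine scaffolds exist on 5-, 6- and 7-membered mono- and bicyclic
carbon frameworks, and how are they distributed over ring size, ring
topology and amine type?*

## Method

1. **Ring systems.** All connected, saturated, all-carbon ring systems of
   circuit rank 1 or 2 whose smallest-set-of-smallest-rings (SSSR) sizes
   lie in {5, 6, 7} are derived analytically: one monocycle per size, one
   spiro and one fused skeleton per unordered size pair, and every
   bridged bicyclo[x.y.z] framework (x ≥ y ≥ z ≥ 1) whose two smallest
   rings (sizes y+z+2 and x+z+2) match a pair. For {5, 6, 7} this gives
   **24 frameworks**: 3 monocyclic, 6 spiro, 6 fused, 9 bridged.
2. **Nitrogen features.** Each framework is decorated with every
   combination of one or two features: ring C → N exchange, and
   exocyclic C–H → C–NH₂ exchange.
3. **Chemical-validity filter.** Products containing a hydrazine (N–N
   bond), an aminal (a carbon with two nitrogen neighbours) or a
   quaternary nitrogen (four heavy-atom bonds) are discarded.
4. **Symmetry deduplication.** Survivors are reduced to one
   representative per constitutional isomer (element-labelled graph
   isomorphism, no stereochemistry) via canonical SMILES keys.
5. **Stratification.** Scaffolds are counted by parent ring sizes, ring
   topology (mono/spiro/fused/bridged) and amine-type profile — the
   multiset of nitrogen classes N (tertiary), NH (secondary), NH₂
   (primary) — and summarised by molecular weight (implicit hydrogens,
   standard average atomic weights).

## Worked example

```python
import aminescaffolds as asc

skels = asc.generate_all({5, 6, 7})
print(len(skels), "ring systems")
scaffolds = asc.enumerate_all(skels)
stats = asc.summary_stats(scaffolds)
print(len(scaffolds), "unique scaffolds")
print(f"MW {stats.mean_mw:.1f} +/- {stats.std_mw:.1f} Da")
table = asc.build_table(scaffolds)
print(table.to_dataframe().loc[["6", "bridged", "total"]].to_string())
```

prints

```
24 ring systems
1139 unique scaffolds
MW 157.2 +/- 22.5 Da
          N  NH  NH2  N/N  N/NH  N/NH2  NH/NH  NH/NH2  NH2/NH2  total
6         0   1    1    0     0      0      1       2        3      8
bridged   9  28   37    3    11     34     37     131      136    426
total    15  76   91    3    20     61    127     388      358   1139
```

The 24 C5–C7 frameworks support 1139 distinct amine/diamine scaffolds
averaging 157 ± 22 Da. Cyclohexane alone carries 8 (the single NH/NH one
is piperazine); bridged bicyclics are the richest stratum (426), and the
only three di-tertiary (N/N) scaffolds are DABCO-like diamines whose
nitrogens sit at non-adjacent bridgeheads — a direct consequence of the
three exclusion rules interacting with bridgehead topology.

The same pipeline is available from the shell:

```sh
amine-scaffolds enumerate --ring-sizes 5,6,7 --out-dir out/
amine-scaffolds tabulate out/scaffolds.smi --out-dir rebuilt/
amine-scaffolds fixtures
```

`enumerate` writes `scaffolds.smi` (canonical SMILES + metadata),
`table.csv` (the stratified count table) and `summary.json`. An optional
`--novel-ref FILE` (one SMILES or canonical key per line) annotates each
scaffold as novel/known against a user-supplied reference list; cells
then render as `novel/total`.

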