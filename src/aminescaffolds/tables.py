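"""Stratified counting and summary statistics for enumerated scaffolds.

The central product is a count table stratifying the scaffold set two
ways at once — by the parent skeleton's SSSR ring sizes (rows "5" ... "7,7")
and by its ring topology (rows "monocyclic" ... "bridged") — against nine
amine-type profile columns plus totals. Each scaffold increments exactly
one size-row cell and one type-row cell, so the size block, the type
block, and the total row are three consistent views of the same set.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .enumeration import COLUMN_KEYS, Scaffold
from .graphs import from_smiles, canonical_key

SIZE_ROWS = ("5", "6", "7", "5,5", "5,6", "5,7", "6,6", "6,7", "7,7")
TYPE_ROWS = ("monocyclic", "spirocyclic", "fused", "bridged")
ROW_KEYS = SIZE_ROWS + TYPE_ROWS + ("total",)
COL_KEYS = COLUMN_KEYS + ("total",)


class EmptyStatsError(ValueError):
    """Raised when summary statistics are requested for an empty scaffold set."""


def _size_row(sc: Scaffold) -> str:
    return ",".join(str(x) for x in sc.parent.ring_sizes)


@dataclass
class CountTable:
    """(row stratum x amine-profile column) scaffold counts with derived totals.

    ``counts`` stores only the base cells (size and type rows x the nine
    profile columns); every total is derived on access, never stored.
    Optional ``novel`` holds parallel novelty counts for rendering
    "novel/total" cells.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    novel: dict[tuple[str, str], int] | None = None

    def cell(self, row: str, col: str) -> int:
        return self._lookup(self.counts, row, col)

    def novel_cell(self, row: str, col: str) -> int:
        if self.novel is None:
            raise ValueError("table has no novelty annotation")
        return self._lookup(self.novel, row, col)

    def _lookup(self, counts, row, col) -> int:
        if row == "total":
            return sum(self._lookup(counts, r, col) for r in SIZE_ROWS)
        if col == "total":
            return sum(counts.get((row, c), 0) for c in COLUMN_KEYS)
        return counts.get((row, col), 0)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            c: [self.cell(r, c) for r in ROW_KEYS] for c in COL_KEYS
        }
        return pd.DataFrame(data, index=list(ROW_KEYS), columns=list(COL_KEYS))

    def to_csv(self, path) -> None:
        """CSV in fixed row/column order; cells are "novel/total" if annotated.

        Ring-size row keys contain commas ("5,6"), so rows are written with
        standard CSV quoting.
        """
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["row", *COL_KEYS])
            for r in ROW_KEYS:
                cells = []
                for c in COL_KEYS:
                    if self.novel is not None:
                        cells.append(f"{self.novel_cell(r, c)}/{self.cell(r, c)}")
                    else:
                        cells.append(str(self.cell(r, c)))
                writer.writerow([r, *cells])

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        counts: dict[tuple[str, str], int] = {}
        novel: dict[tuple[str, str], int] = {}
        annotated = False
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            cols = next(reader)[1:]
            for parts in reader:
                row = parts[0]
                if row == "total":
                    continue
                for col, cell in zip(cols, parts[1:]):
                    if col == "total":
                        continue
                    if "/" in cell:
                        annotated = True
                        nov, tot = cell.split("/")
                        novel[(row, col)] = int(nov)
                        counts[(row, col)] = int(tot)
                    else:
                        counts[(row, col)] = int(cell)
        counts = {k: v for k, v in counts.items() if v}
        novel = {k: v for k, v in novel.items() if v}
        return cls(counts=counts, novel=novel if annotated else None)


def build_table(scaffolds) -> CountTable:
    """Count scaffolds into the (ring-size row, type row) x profile layout."""
    counts: dict[tuple[str, str], int] = {}
    for sc in scaffolds:
        if sc.profile not in COLUMN_KEYS:
            raise ValueError(f"malformed amine profile {sc.profile!r}")
        for row in (_size_row(sc), sc.parent.ring_type.value):
            counts[(row, sc.profile)] = counts.get((row, sc.profile), 0) + 1
    return CountTable(counts=counts)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean_mw: float
    std_mw: float


def summary_stats(scaffolds) -> SummaryStats:
    """Count, mean and population standard deviation of molecular weight."""
    weights = [sc.formula.weight for sc in scaffolds]
    if not weights:
        raise EmptyStatsError("no scaffolds; statistics undefined")
    n = len(weights)
    mean = sum(weights) / n
    var = sum((w - mean) ** 2 for w in weights) / n
    return SummaryStats(n=n, mean_mw=mean, std_mw=math.sqrt(var))


def annotate_novelty(scaffolds, reference):
    """Flag scaffolds absent from a user-supplied reference list.

    ``reference`` is an iterable of canonical keys or SMILES strings;
    SMILES entries are canonicalized before comparison. Unparseable
    entries are skipped with a count. Returns
    (flags: dict key -> bool novel, skipped: int).
    """
    ref_keys = set()
    skipped = 0
    for entry in reference:
        entry = entry.strip()
        if not entry:
            continue
        try:
            ref_keys.add(canonical_key(from_smiles(entry)))
        except Exception:
            skipped += 1
    flags = {sc.key: sc.key not in ref_keys for sc in scaffolds}
    return flags, skipped


def build_annotated_table(scaffolds, flags) -> CountTable:
    """Count table carrying parallel novel counts per cell."""
    table = build_table(scaffolds)
    novel: dict[tuple[str, str], int] = {}
    for sc in scaffolds:
        if not flags.get(sc.key, True):
            continue
        for row in (_size_row(sc), sc.parent.ring_type.value):
            novel[(row, sc.profile)] = novel.get((row, sc.profile), 0) + 1
    table.novel = novel
    return table


def write_outputs(table, stats, scaffolds, csv_path, smiles_path, json_path):
    """Write the count-table CSV, the scaffold SMILES file, and a JSON summary."""
    from .enumeration import write_scaffolds

    table.to_csv(csv_path)
    write_scaffolds(scaffolds, smiles_path)
    summary = {
        "n": stats.n,
        "mean_mw": round(stats.mean_mw, 1),
        "std_mw": round(stats.std_mw, 1),
        "row_totals": {r: table.cell(r, "total") for r in ROW_KEYS},
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
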