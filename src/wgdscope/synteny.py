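"""Microsynteny conservation scoring across assemblies.

Gene duplicates born in a whole-genome duplication sit inside duplicated
blocks, so their local gene neighbourhoods should be mirrored in other
assemblies of the genus.  This module derives dense gene-order ordinals
from position tables, then asks, for each anchor orthogroup, whether its
reference neighbourhood is preserved around the anchor's counterpart in
every other assembly.  An anchor duplicated in one assembly (a 2:1:1
orthogroup) must pass the test around BOTH copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._rounding import round_half_up


@dataclass(frozen=True)
class SyntenyGene:
    assembly: str
    scaffold: str
    ordinal: int  # dense 0-based rank along the scaffold's gene order
    og_id: str
    copy_tag: str = ""


@dataclass(frozen=True)
class ConservationCall:
    og_id: str
    cls: str  # "2:1:1" or "1:1:1"
    breaks: tuple[tuple[str, str], ...]  # (assembly, reason)

    @property
    def conserved(self) -> bool:
        return len(self.breaks) == 0


def build_gene_orders(positions: pd.DataFrame) -> list[SyntenyGene]:
    """Assign dense per-scaffold ordinals from start coordinates.

    ``positions`` needs columns assembly, scaffold, start, og_id and
    (optionally) copy_tag.  Within each (assembly, scaffold), genes are
    sorted by start coordinate, ties broken by og_id lexicographically,
    and numbered 0..n-1.  Exact duplicate rows are a fatal error.
    """
    df = positions.copy()
    if "copy_tag" not in df.columns:
        df["copy_tag"] = ""
    df["copy_tag"] = df["copy_tag"].fillna("")
    key_cols = ["assembly", "scaffold", "start", "og_id", "copy_tag"]
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(
            f"duplicate gene-position row: {tuple(dup[key_cols])}"
        )
    genes: list[SyntenyGene] = []
    for (assembly, scaffold), grp in df.groupby(["assembly", "scaffold"], sort=True):
        grp = grp.sort_values(["start", "og_id", "copy_tag"], kind="mergesort")
        for ordinal, row in enumerate(grp.itertuples(index=False)):
            genes.append(
                SyntenyGene(
                    assembly=str(assembly),
                    scaffold=str(scaffold),
                    ordinal=ordinal,
                    og_id=str(row.og_id),
                    copy_tag=str(row.copy_tag),
                )
            )
    return genes


def _index_orders(orders: Sequence[SyntenyGene]):
    """(assembly -> og_id -> [genes]) and (assembly, scaffold) -> ordered genes."""
    by_og: dict[str, dict[str, list[SyntenyGene]]] = {}
    by_scaffold: dict[tuple[str, str], list[SyntenyGene]] = {}
    for g in orders:
        by_og.setdefault(g.assembly, {}).setdefault(g.og_id, []).append(g)
        by_scaffold.setdefault((g.assembly, g.scaffold), []).append(g)
    for genes in by_scaffold.values():
        genes.sort(key=lambda g: g.ordinal)
    return by_og, by_scaffold


def _reference_neighbors(
    anchor_gene: SyntenyGene,
    scaffold_genes: Sequence[SyntenyGene],
    window: int,
) -> tuple[list[str], list[str]]:
    """Up to ``window`` nearest orthogroup-bearing neighbours per side."""
    idx = anchor_gene.ordinal
    left = [g.og_id for g in scaffold_genes[max(0, idx - window):idx]]
    right = [g.og_id for g in scaffold_genes[idx + 1: idx + 1 + window]]
    return left, right


def _neighborhood_ok(
    left: Sequence[str],
    right: Sequence[str],
    counterpart: SyntenyGene,
    scaffold_genes: Sequence[SyntenyGene],
    window: int,
) -> tuple[bool, int]:
    """Check one counterpart's neighbourhood.

    Conserved iff, per side, at least (available - 1) of the reference
    neighbours occur within a span of 2*window+1 gene positions centred
    on the counterpart, orientation-insensitive (an inverted block still
    counts).  Returns (ok, total neighbours found in the span).
    """
    span = 2 * window + 1
    lo = counterpart.ordinal - span
    hi = counterpart.ordinal + span
    nearby = {
        g.og_id
        for g in scaffold_genes
        if lo <= g.ordinal <= hi and g.ordinal != counterpart.ordinal
    }
    found_total = 0
    ok = True
    for side in (left, right):
        found = sum(1 for og in side if og in nearby)
        found_total += found
        if side and found < len(side) - 1:
            ok = False
    return ok, found_total


def conserved_microsynteny(
    anchor: str,
    orders: Sequence[SyntenyGene],
    window: int = 5,
    reference_assembly: str = "reference",
) -> ConservationCall:
    """Call microsynteny conservation for one anchor orthogroup.

    The anchor's neighbourhood (``window`` orthogroup-bearing genes per
    side) in the reference assembly is sought in every other assembly;
    if the anchor has two copies in an assembly, both copies'
    neighbourhoods must pass.  Missing anchors record an "absent" break,
    neighbourhoods with essentially no reference neighbours nearby a
    "translocated" break, and partial failures a "rearranged" break.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_og, by_scaffold = _index_orders(orders)
    if reference_assembly not in by_og or anchor not in by_og[reference_assembly]:
        raise KeyError(f"anchor {anchor!r} not found in {reference_assembly!r}")
    ref_gene = by_og[reference_assembly][anchor][0]
    ref_scaffold = by_scaffold[(reference_assembly, ref_gene.scaffold)]
    left, right = _reference_neighbors(ref_gene, ref_scaffold, window)

    n_copies_max = max(
        len(genes.get(anchor, [])) for genes in by_og.values()
    )
    cls = "2:1:1" if n_copies_max >= 2 else "1:1:1"

    breaks: list[tuple[str, str]] = []
    for assembly in sorted(by_og):
        if assembly == reference_assembly:
            continue
        copies = by_og[assembly].get(anchor, [])
        if not copies:
            breaks.append((assembly, "absent"))
            continue
        for counterpart in copies:
            scaffold_genes = by_scaffold[(assembly, counterpart.scaffold)]
            ok, found = _neighborhood_ok(
                left, right, counterpart, scaffold_genes, window
            )
            if not ok:
                reason = "translocated" if found == 0 else "rearranged"
                breaks.append((assembly, reason))
                break  # one failing copy breaks the whole assembly
    return ConservationCall(og_id=anchor, cls=cls, breaks=tuple(breaks))


def synteny_fractions(
    calls: Sequence[ConservationCall],
) -> dict[str, tuple[int, int, int]]:
    """Per-class (conserved, total, percent) with half-up integer percent."""
    if not calls:
        raise ValueError("no conservation calls to summarize")
    out: dict[str, tuple[int, int, int]] = {}
    classes = sorted({c.cls for c in calls})
    for cls in classes:
        total = sum(1 for c in calls if c.cls == cls)
        conserved = sum(1 for c in calls if c.cls == cls and c.conserved)
        pct = int(round_half_up(100.0 * conserved / total, 0))
        out[cls] = (conserved, total, pct)
    return out
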