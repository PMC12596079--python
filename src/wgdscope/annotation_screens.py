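"""Annotation-derived screens: meiosis-gene inventory, TE bursts, repeat landscapes.

Three small, rule-based screens that accompany the sequence-level
evidence for whole-genome duplication:

* a gene-inventory matrix counting, per gene and assembly, how many
  annotated copies cover at least 80% of the query protein's length;
* a transposable-element "burst" filter flagging families whose copy
  number in the focal species exceeds a relative's by at least 100
  copies and at least 5-fold;
* repeat-landscape binning of TE base pairs by within-family Kimura
  divergence, where a dominant young (0-2%) bin marks recent activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up


@dataclass(frozen=True)
class InventoryHit:
    """One annotated copy of a query gene in one assembly."""

    gene: str
    assembly: str
    hit_length: int   # residues
    query_length: int  # residues
    provenance: str = "annotation"  # e.g. "annotation" or "secondary-search"
    copy_seq: str | None = None

    def __post_init__(self) -> None:
        if self.hit_length <= 0 or self.query_length <= 0:
            raise ValueError("hit and query lengths must be positive")


@dataclass(frozen=True)
class TEFamilyRecord:
    """Read-depth-estimated copy numbers of one TE family per species."""

    family: str
    copies: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.copies.values()):
            raise ValueError(f"{self.family}: negative copy number")


def copy_count(hits: Sequence[InventoryHit], min_cov: float = 0.8) -> int:
    """Copies covering at least ``min_cov`` of the query length.

    All hits must refer to one (gene, assembly) cell; an empty hit list
    means the gene is absent (0 copies).
    """
    if hits:
        keys = {(h.gene, h.assembly) for h in hits}
        if len(keys) > 1:
            raise ValueError(f"hits span multiple gene/assembly cells: {keys}")
    return sum(1 for h in hits if h.hit_length >= min_cov * h.query_length)


def inventory_matrix(
    genes: Sequence[str],
    assemblies: Sequence[str],
    hits: Sequence[InventoryHit],
    min_cov: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """Copy-count matrix plus presence/multicopy summary.

    The gene and assembly universes are declared up front so absence is
    representable.  A gene is *present* in an assembly iff it has >= 1
    qualifying copy; *multicopy* iff >= 2.  The summary reports, for the
    first assembly column (or pooled over assemblies when there is only
    one), n_present / n_queried with a half-up integer percent, and the
    multicopy share among present genes as a two-decimal fraction.
    Duplicate hit rows (identical fields) are collapsed.
    """
    gene_set = set(genes)
    for h in hits:
        if h.gene not in gene_set:
            raise KeyError(f"hit references undeclared gene {h.gene!r}")
        if h.assembly not in set(assemblies):
            raise KeyError(f"hit references undeclared assembly {h.assembly!r}")
    unique_hits = list(dict.fromkeys(hits))
    cells: dict[tuple[str, str], list[InventoryHit]] = {}
    for h in unique_hits:
        cells.setdefault((h.gene, h.assembly), []).append(h)
    matrix = pd.DataFrame(
        [
            [copy_count(cells.get((g, a), []), min_cov) for a in assemblies]
            for g in genes
        ],
        index=list(genes),
        columns=list(assemblies),
    )
    # presence pooled over assemblies: present anywhere counts as present
    present_mask = (matrix >= 1).any(axis=1)
    n_present = int(present_mask.sum())
    n_queried = len(genes)
    multicopy_mask = (matrix >= 2).any(axis=1) & present_mask
    n_multicopy = int(multicopy_mask.sum())
    summary = {
        "n_present": n_present,
        "n_queried": n_queried,
        "percent_present": int(
            round_half_up(100.0 * n_present / n_queried, 0) if n_queried else 0
        ),
        "n_multicopy": n_multicopy,
        "multicopy_fraction": (
            round_half_up(n_multicopy / n_present, 2) if n_present else 0.0
        ),
    }
    return matrix, summary


def te_relative_abundance(
    rec: TEFamilyRecord, a: str, b: str
) -> tuple[float, bool]:
    """copies[a] / copies[b] rounded to one decimal.

    Returns (ratio, is_finite); a zero denominator reports
    (inf, False) instead of raising.
    """
    denom = rec.copies[b]
    numer = rec.copies[a]
    if denom == 0:
        return float("inf"), False
    return round_half_up(numer / denom, 1), True


def te_burst_filter(
    records: Sequence[TEFamilyRecord],
    focal: str,
    other: str,
    min_copy_diff: float = 100.0,
    min_fold: float = 5.0,
) -> list[str]:
    """Families with a focal-specific activity burst.

    Retained iff copies[focal] - copies[other] >= min_copy_diff AND
    copies[focal]/copies[other] >= min_fold.  A zero denominator passes
    the fold criterion whenever the difference criterion passes.
    """
    kept = []
    for r in records:
        if focal not in r.copies or other not in r.copies:
            raise KeyError(f"{r.family}: species {focal!r}/{other!r} missing")
        f, o = r.copies[focal], r.copies[other]
        if f - o < min_copy_diff:
            continue
        if o == 0 or f / o >= min_fold:
            kept.append(r.family)
    return kept


def burst_intersection(*burst_lists: Sequence[str]) -> list[str]:
    """Families called as bursts in every pairwise comparison supplied."""
    if not burst_lists:
        return []
    common = set(burst_lists[0])
    for lst in burst_lists[1:]:
        common &= set(lst)
    return sorted(common)


def kimura_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions.

    d = -(1/2) ln((1-2P-Q) * sqrt(1-2Q)).  Raises on saturated input
    (arguments outside the model's domain).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturated: P/Q outside the K2P domain")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def landscape_bins(
    copies: Iterable[tuple[float, float]],
    genome_size: float,
    bin_width: float = 0.01,
    max_divergence: float = 0.5,
) -> pd.DataFrame:
    """Bin TE base pairs by divergence; report percent of genome per bin.

    ``copies`` yields (divergence, bp) pairs; divergence is a fraction
    (0.02 == 2%).  Bins are [i*w, (i+1)*w) with the final bin closed.
    Returns a DataFrame (bin_low, bin_high, bp, genome_percent) covering
    [0, max_divergence] even when empty.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n_bins = int(np.ceil(max_divergence / bin_width))
    bp = np.zeros(n_bins)
    for divergence, length in copies:
        if divergence < 0:
            raise ValueError(f"negative divergence {divergence}")
        idx = min(int(divergence / bin_width), n_bins - 1)
        bp[idx] += length
    lows = np.arange(n_bins) * bin_width
    return pd.DataFrame(
        {
            "bin_low": lows,
            "bin_high": lows + bin_width,
            "bp": bp,
            "genome_percent": 100.0 * bp / genome_size,
        }
    )


def young_to_mid_ratio(
    bins: pd.DataFrame,
    young: tuple[float, float] = (0.0, 0.02),
    mid: tuple[float, float] = (0.03, 0.05),
) -> float:
    """Ratio of genome percent in young vs mid divergence bins.

    Default windows compare the 0-2% divergence mass with the 3-5% mass;
    a ratio above ~2 marks a recent genome-wide burst of TE activity.
    Bins are selected by their lower edge (inclusive on both ends).
    """
    sel_young = bins[(bins.bin_low >= young[0]) & (bins.bin_low <= young[1])]
    sel_mid = bins[(bins.bin_low >= mid[0]) & (bins.bin_low <= mid[1])]
    denom = sel_mid.genome_percent.sum()
    if denom == 0:
        return float("inf")
    return float(sel_young.genome_percent.sum() / denom)
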