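"""Orthogroup copy-number patterns and gene-family filters.

A whole-genome duplication doubles gene content instantaneously, so a
focal lineage that underwent one should show an excess of homology
groups with two focal copies but one copy in each close relative
("2:1:1" in species order focal : relative1 : relative2) over the
analogous patterns centred on the relatives (1:2:1, 1:1:2).  This module
reads OrthoFinder-dialect gene-count tables, classifies each orthogroup
by pattern, tallies pattern classes, tests focal duplication enrichment
with Fisher's exact test, and applies the expansion filters used to pick
candidate gene families for downstream enrichment analysis.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._rounding import round_half_up

logger = logging.getLogger(__name__)


@dataclass
class OrthogroupRecord:
    """Per-species gene counts (and optionally gene ids) for one orthogroup."""

    og_id: str
    counts: dict[str, int]
    gene_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, ids in self.gene_ids.items():
            if sp in self.counts and self.counts[sp] != len(ids):
                raise ValueError(
                    f"{self.og_id}: count for {sp} disagrees with gene id list"
                )
        if all(c < 1 for c in self.counts.values()):
            raise ValueError(f"{self.og_id}: orthogroup empty in every species")


@dataclass(frozen=True)
class PatternClass:
    """Copy-number pattern over an ordered species tuple.

    Categories are 0, 1, 2 and "multi" (>2 copies); the label renders
    them colon-separated in species order, e.g. "2:1:1".
    """

    pattern: tuple[str, ...]
    label: str


def read_genecount_table(path: str | os.PathLike) -> list[OrthogroupRecord]:
    """Parse an Orthogroups.GeneCount.tsv-dialect table.

    First column holds orthogroup ids, remaining columns one species
    each; a trailing "Total" column is ignored.  Negative or non-integer
    counts are a fatal parse error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    species = [c for c in df.columns[1:] if c.lower() != "total"]
    records = []
    for i, row in df.iterrows():
        counts = {}
        for sp in species:
            raw = row[sp]
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i + 2}: non-integer count {raw!r} for {sp}"
                ) from None
            if val < 0:
                raise ValueError(f"row {i + 2}: negative count for {sp}")
            counts[sp] = val
        records.append(OrthogroupRecord(og_id=str(row[id_col]), counts=counts))
    return records


def _category(count: int) -> str:
    return "multi" if count >= 3 else str(count)


def classify_pattern(
    record: OrthogroupRecord, species_order: Sequence[str]
) -> PatternClass:
    """Deterministic pattern label in the given species order."""
    missing = [sp for sp in species_order if sp not in record.counts]
    if missing:
        raise KeyError(f"{record.og_id}: no counts for species {missing}")
    cats = tuple(_category(record.counts[sp]) for sp in species_order)
    return PatternClass(pattern=cats, label=":".join(cats))


def count_patterns(
    records: Sequence[OrthogroupRecord], species_order: Sequence[str]
) -> pd.DataFrame:
    """Tally orthogroups per pattern label.

    Returns a DataFrame (label, count, proportion, percent) where
    proportions are taken against the full orthogroup total and percents
    are half-up rounded to one decimal.  Counts partition the table:
    they always sum to ``len(records)``.
    """
    if not records:
        raise ValueError("empty record list")
    tally: dict[str, int] = {}
    for rec in records:
        label = classify_pattern(rec, species_order).label
        tally[label] = tally.get(label, 0) + 1
    total = len(records)
    rows = [
        {
            "label": label,
            "count": c,
            "proportion": c / total,
            "percent": round_half_up(100.0 * c / total, 1),
        }
        for label, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def duplication_enrichment(
    records: Sequence[OrthogroupRecord],
    focal: str,
    others: tuple[str, str],
) -> dict:
    """Fisher's exact test for focal-specific duplication excess.

    The 2x2 table compares the focal 2:1:1 class against the pooled
    analogous classes of the two other species (1:2:1 plus 1:1:2), with
    the non-duplicated margin for the pooled side summed over both
    species so per-species exposure stays comparable.  Orthogroups where
    the focal species is absent are excluded from the focal margin (they
    carry no information about focal duplication); likewise per other
    species.  Odds ratio is the conditional ML estimate with an exact
    95% CI.
    """
    from scipy.stats import fisher_exact
    from scipy.stats.contingency import odds_ratio

    o1, o2 = others
    order = (focal, o1, o2)

    def is_dup_pattern(rec: OrthogroupRecord, dup_sp: str) -> bool:
        return all(
            rec.counts.get(sp, 0) == (2 if sp == dup_sp else 1) for sp in order
        )

    n_focal_dup = sum(is_dup_pattern(r, focal) for r in records)
    n_o1_dup = sum(is_dup_pattern(r, o1) for r in records)
    n_o2_dup = sum(is_dup_pattern(r, o2) for r in records)
    n_focal_margin = sum(r.counts.get(focal, 0) >= 1 for r in records)
    n_o1_margin = sum(r.counts.get(o1, 0) >= 1 for r in records)
    n_o2_margin = sum(r.counts.get(o2, 0) >= 1 for r in records)

    a = n_focal_dup
    b = n_focal_margin - n_focal_dup
    c = n_o1_dup + n_o2_dup
    d = (n_o1_margin - n_o1_dup) + (n_o2_margin - n_o2_dup)
    table = [[a, b], [c, d]]

    if min(a, b, c, d) == 0:
        # degenerate margin: report a one-sided p and an unbounded OR
        _, p = fisher_exact(table, alternative="greater")
        est = float("inf") if (a > 0 and (c == 0 or d == 0 or b == 0)) else 0.0
        return {
            "table": table, "odds_ratio": est,
            "ci_low": float("nan"), "ci_high": float("nan"),
            "p_value": float(p), "degenerate": True,
        }
    res = odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    _, p = fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(res.statistic),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "p_value": float(p),
        "degenerate": False,
    }


def expanded_filter(
    records: Sequence[OrthogroupRecord], focal: str, others: tuple[str, str]
) -> list[str]:
    """Orthogroups where the focal count strictly exceeds double each other.

    Retained iff focal_count > 2 * count_s for BOTH other species — more
    copies than a single whole-genome duplication alone would leave.
    """
    kept = []
    for r in records:
        fc = r.counts.get(focal, 0)
        if all(fc > 2 * r.counts.get(sp, 0) for sp in others):
            kept.append(r.og_id)
    return kept


def cafe_prefilter(
    records5: Sequence[OrthogroupRecord],
    focal: str,
    significant: Mapping[str, bool] | None = None,
) -> list[str]:
    """Pre-filter for birth-death gene-family testing over five species.

    Retained iff the focal count exceeds the maximum other-species count
    by >= 3 (an increase larger than WGD alone provides) AND every one of
    the five species has >= 1 copy.  When a per-orthogroup significance
    flag from an external family-size test is supplied it is applied as a
    third criterion; otherwise the two implementable criteria run alone
    with a logged notice.
    """
    if significant is None:
        logger.info(
            "no external significance column supplied; filtering on copy-number "
            "criteria only"
        )
    kept = []
    for r in records5:
        counts = r.counts
        other = [c for sp, c in counts.items() if sp != focal]
        if len(other) != len(counts) - 1 or focal not in counts:
            raise KeyError(f"{r.og_id}: focal species {focal!r} missing")
        if counts[focal] - max(other) < 3:
            continue
        if min(counts.values()) < 1:
            continue
        if significant is not None and not significant.get(r.og_id, False):
            continue
        kept.append(r.og_id)
    return kept
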