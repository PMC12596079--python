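"""Paralog divergence from gene trees and aligned sequences.

Duplicates born in one whole-genome duplication all share a single age,
so their pairwise divergences pile up in a narrow peak; duplicates from
the background duplication process scatter.  Given quartet gene trees
(two copies in the duplicated species plus one copy in each of two
relatives), this module computes the patristic distance between the two
copies (homoeolog divergence) and the mean distance from the copies to
each relative (ortholog divergence), summarizes distributions by median
and 2.5/97.5 percentiles, locates modal ("peak") divergence by kernel
density, and computes nucleotide p-distance between aligned copies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class QuartetSummary:
    og_id: str
    duplicated_species: str
    paralog_div: float
    div_to_other: dict[str, float]


@dataclass(frozen=True)
class DistanceSummary:
    median: float
    ci_low: float   # 2.5th percentile
    ci_high: float  # 97.5th percentile
    n: int


def read_trees(
    source: str | os.PathLike, species_delim: str = "|"
) -> list[dendropy.Tree]:
    """Read newick trees from a file (one or more trees) or directory."""
    paths: list[str]
    src = os.fspath(source)
    if os.path.isdir(src):
        paths = sorted(
            os.path.join(src, f) for f in os.listdir(src)
            if f.endswith((".nwk", ".newick", ".tre", ".tree"))
        )
    else:
        paths = [src]
    trees: list[dendropy.Tree] = []
    for p in paths:
        tl = dendropy.TreeList.get(path=p, schema="newick")
        trees.extend(tl)
    return trees


def leaf_species(label: str, species_delim: str = "|") -> str:
    """Species tag = leaf-name prefix before the delimiter."""
    return label.split(species_delim, 1)[0]


def patristic_distance(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    if leaf_a == leaf_b:
        if tree.taxon_namespace.get_taxon(leaf_a) is None and not _find_node(
            tree, leaf_a
        ):
            raise KeyError(f"leaf {leaf_a!r} not in tree")
        return 0.0
    node_a = _find_node(tree, leaf_a)
    node_b = _find_node(tree, leaf_b)
    if node_a is None:
        raise KeyError(f"leaf {leaf_a!r} not in tree")
    if node_b is None:
        raise KeyError(f"leaf {leaf_b!r} not in tree")
    # walk both leaves to the root, recording cumulative lengths
    anc_a: dict[int, float] = {}
    node, dist = node_a, 0.0
    while node is not None:
        anc_a[id(node)] = dist
        dist += node.edge.length or 0.0
        node = node.parent_node
    node, dist = node_b, 0.0
    while node is not None:
        if id(node) in anc_a:
            return anc_a[id(node)] + dist
        dist += node.edge.length or 0.0
        node = node.parent_node
    raise RuntimeError("leaves share no common ancestor (disconnected tree)")


def _find_node(tree: dendropy.Tree, label: str):
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    return None


def quartet_summary(
    tree: dendropy.Tree, species_delim: str = "|", og_id: str = ""
) -> QuartetSummary:
    """Summarize one 2+1+1 quartet gene tree.

    Exactly one species must contribute two leaves and two species one
    leaf each.  ``paralog_div`` is the patristic distance between the
    duplicated species' copies; divergence to each other species is the
    mean of the two copies' distances to that species' leaf.
    """
    by_species: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        by_species.setdefault(leaf_species(label, species_delim), []).append(label)
    dup = [sp for sp, leaves in by_species.items() if len(leaves) == 2]
    singles = [sp for sp, leaves in by_species.items() if len(leaves) == 1]
    if len(dup) != 1 or len(singles) != 2 or len(by_species) != 3:
        composition = {sp: len(v) for sp, v in by_species.items()}
        raise ValueError(
            "expected a 2+1+1 quartet (one duplicated species, two single-copy "
            f"species); got {composition}"
        )
    copy1, copy2 = by_species[dup[0]]
    div_to_other = {}
    for sp in singles:
        other_leaf = by_species[sp][0]
        d1 = patristic_distance(tree, copy1, other_leaf)
        d2 = patristic_distance(tree, copy2, other_leaf)
        div_to_other[sp] = 0.5 * (d1 + d2)
    return QuartetSummary(
        og_id=og_id,
        duplicated_species=dup[0],
        paralog_div=patristic_distance(tree, copy1, copy2),
        div_to_other=div_to_other,
    )


def triplet_distances(
    tree: dendropy.Tree, species_delim: str = "|"
) -> dict[tuple[str, str], float]:
    """All pairwise patristic distances of a 1:1:1 triplet tree.

    Only one unrooted topology exists for three taxa, so branch lengths
    are the whole story; keys are sorted species pairs.
    """
    leaves = {
        leaf_species(l.taxon.label, species_delim): l.taxon.label
        for l in tree.leaf_node_iter()
    }
    if len(leaves) != 3:
        raise ValueError("expected exactly three species, one leaf each")
    out = {}
    species = sorted(leaves)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            out[(a, b)] = patristic_distance(tree, leaves[a], leaves[b])
    return out


def summarize_distances(values: Sequence[float]) -> DistanceSummary:
    """Median with a 2.5th–97.5th percentile envelope.

    Percentiles use linear interpolation; below n = 40 the envelope
    clamps to the observed min/max (the interpolated tails would
    extrapolate from too few points to mean anything).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distance list")
    med = float(np.median(arr))
    if arr.size < 40:
        lo, hi = float(arr.min()), float(arr.max())
    else:
        lo = float(np.percentile(arr, 2.5))
        hi = float(np.percentile(arr, 97.5))
    return DistanceSummary(median=med, ci_low=lo, ci_high=hi, n=int(arr.size))


def kde_peak(
    values: Sequence[float], bandwidth: float | str = "silverman"
) -> float:
    """Modal value by Gaussian KDE on a fixed 10,000-point grid.

    The grid spans [0, max*1.05]; a numeric ``bandwidth`` is an absolute
    kernel sd, the default is Silverman's rule.  All-equal input returns
    that value directly.
    """
    from scipy.stats import gaussian_kde

    arr = np.asarray(values, dtype=float)
    if arr.size < 10:
        raise ValueError("need >= 10 values for a peak estimate")
    if np.ptp(arr) == 0.0:
        return float(arr[0])
    if bandwidth == "silverman":
        kde = gaussian_kde(arr, bw_method="silverman")
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
        kde = gaussian_kde(arr, bw_method=bw / arr.std(ddof=1))
    grid = np.linspace(0.0, float(arr.max()) * 1.05, 10_000)
    return float(grid[int(np.argmax(kde(grid)))])


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing nucleotides between two aligned sequences.

    Positions where either sequence has a gap or an ambiguity code
    (anything but A/C/G/T, case-insensitive) are excluded from both the
    numerator and the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) == 0:
        raise ValueError("empty alignment")
    compared = 0
    mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _ACGT and b in _ACGT:
            compared += 1
            if a != b:
                mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (unambiguous, ungapped) sites")
    return mismatches / compared


def mean_pairwise_p_distance(seqs: Sequence[str]) -> float:
    """Mean p-distance over all copy pairs (multi-copy gene summary)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    vals = [
        p_distance(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return float(np.mean(vals))
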