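"""Allele balance at heterozygous sites.

A single individual's read data carry a ploidy signal: at a heterozygous
site a diploid is expected to show roughly equal read depth for the two
alleles (minor-allele fraction near 0.5), a triploid shows 2:1 / 1:2
dosage (fraction near 1/3), and a tetraploid can show 3:1, 2:2 and 1:3
dosage (fractions near 1/4 and 1/2).  This module extracts per-allele
depths at heterozygous biallelic sites from a VCF, computes minor-allele
fractions, and tallies them in the diagnostic windows used to summarize
the spectrum (diploid [0.45, 0.5], triploid [0.305, 0.355], tetraploid
[0.225, 0.275]).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._rounding import round_half_up

logger = logging.getLogger(__name__)

#: The three diagnostic minor-allele-fraction windows, in ploidy order.
DIPLOID_WINDOW = (0.45, 0.5)
TRIPLOID_WINDOW = (0.305, 0.355)
TETRAPLOID_WINDOW = (0.225, 0.275)
DEFAULT_WINDOWS = (TETRAPLOID_WINDOW, TRIPLOID_WINDOW, DIPLOID_WINDOW)


@dataclass(frozen=True)
class AlleleDepthSite:
    """One heterozygous biallelic site with per-allele read depths."""

    scaffold: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth_ref: int
    depth_alt: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")
        if self.position < 1:
            raise ValueError("position must be 1-based (>= 1)")
        if self.depth_ref < 0 or self.depth_alt < 0:
            raise ValueError("depths must be non-negative")


@dataclass(frozen=True)
class MAFSpectrum:
    """Counts of minor-allele fractions falling in named windows."""

    window_edges: tuple[tuple[float, float], ...]
    window_counts: tuple[int, ...]
    total_sites: int

    @property
    def window_proportions(self) -> tuple[float, ...]:
        return tuple(c / self.total_sites for c in self.window_counts)

    def window_percents(self, decimals: int = 1) -> tuple[float, ...]:
        """Window proportions rendered as half-up-rounded percentages."""
        return tuple(
            round_half_up(100.0 * c / self.total_sites, decimals)
            for c in self.window_counts
        )


def minor_allele_fraction(site: AlleleDepthSite) -> float:
    """Depth of the rarer allele over total depth; in (0, 0.5]."""
    total = site.depth_ref + site.depth_alt
    if total <= 0:
        raise ValueError("zero total depth at %s:%d" % (site.scaffold, site.position))
    return min(site.depth_ref, site.depth_alt) / total


def _depths_from_variant(variant, sample_idx: int):
    """Per-allele (ref, alt) depth for one cyvcf2 variant, or None.

    Prefers the per-sample AD field; falls back to the INFO DP4 quadruple
    (forward+reverse summed per allele), which is what older samtools/GATK
    pipelines emit.
    """
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        row = ad[sample_idx]
        if len(row) >= 2 and row[0] >= 0 and row[1] >= 0:
            return int(row[0]), int(row[1])
    dp4 = variant.INFO.get("DP4")
    if dp4 is not None and len(dp4) == 4:
        return int(dp4[0]) + int(dp4[1]), int(dp4[2]) + int(dp4[3])
    return None


def load_het_sites(
    vcf_path: str | os.PathLike,
    min_total_depth: int = 10,
    min_genotype_quality: int = 20,
    sample: str | None = None,
) -> list[AlleleDepthSite]:
    """Read heterozygous biallelic sites with allele depths from a VCF.

    Multiallelic and homozygous records are dropped; sites whose summed
    allele depth is below ``min_total_depth`` or whose genotype quality is
    below ``min_genotype_quality`` are dropped.  Heterozygosity is taken
    from the genotype call, not re-derived from depths.  Records lacking
    any depth annotation are skipped with a warning.
    """
    from cyvcf2 import VCF

    if not os.path.exists(os.fspath(vcf_path)):
        raise FileNotFoundError(f"VCF not readable: {vcf_path}")
    vcf = VCF(os.fspath(vcf_path))
    if sample is None:
        sample_idx = 0
    else:
        sample_idx = vcf.samples.index(sample)

    sites: list[AlleleDepthSite] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = v.genotypes[sample_idx] if v.genotypes else None
        if gt is None or len(gt) < 2:
            continue
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if len(alleles) < 2 or len(set(alleles)) < 2:
            continue  # homozygous, haploid or missing call
        if min_genotype_quality > 0:
            try:
                gq = v.gt_quals[sample_idx]
            except Exception:
                gq = None
            if gq is not None and gq >= 0 and gq < min_genotype_quality:
                continue
        depths = _depths_from_variant(v, sample_idx)
        if depths is None:
            logger.warning(
                "no AD/DP4 depth annotation at %s:%d; record skipped", v.CHROM, v.POS
            )
            continue
        d_ref, d_alt = depths
        if d_ref + d_alt < min_total_depth:
            continue
        sites.append(
            AlleleDepthSite(
                scaffold=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                depth_ref=d_ref,
                depth_alt=d_alt,
            )
        )
    return sites


def _check_windows(windows: Sequence[Sequence[float]]) -> list[tuple[float, float]]:
    clean = []
    for lo, hi in windows:
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"window [{lo}, {hi}] outside [0, 0.5]")
        clean.append((float(lo), float(hi)))
    ordered = sorted(clean)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if lo2 < hi1:  # closed windows sharing an endpoint also overlap
            raise ValueError(f"windows [{lo1},{hi1}] and [{lo2},{hi2}] overlap")
    return clean


def bin_spectrum(
    sites: Sequence[AlleleDepthSite],
    windows: Sequence[Sequence[float]] = DEFAULT_WINDOWS,
) -> MAFSpectrum:
    """Count minor-allele fractions in closed windows.

    A fraction f is counted in window [lo, hi] iff lo <= f <= hi (closed on
    both ends).  ``total_sites`` is the number of input sites, not the sum
    of window counts — the windows need not tile [0, 0.5].
    """
    clean = _check_windows(windows)
    if len(sites) == 0:
        raise ValueError("cannot bin an empty site list")
    fracs = np.array([minor_allele_fraction(s) for s in sites])
    counts = tuple(int(np.sum((fracs >= lo) & (fracs <= hi))) for lo, hi in clean)
    return MAFSpectrum(
        window_edges=tuple(clean), window_counts=counts, total_sites=len(sites)
    )


def spectrum_density(
    fractions: Iterable[float], bandwidth: float | None = None, grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of minor-allele fractions on [0, 0.5].

    Returns ``(grid, density)``.  ``bandwidth`` is an absolute kernel sd;
    ``None`` uses Silverman's rule.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(list(fractions), dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values for a density")
    if bandwidth is None:
        kde = gaussian_kde(x, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    grid = np.linspace(0.0, 0.5, grid_size)
    return grid, kde(grid)


def write_spectrum_tsv(spectrum: MAFSpectrum, path: str | os.PathLike) -> None:
    """Write window_low, window_high, count, total, percent as TSV."""
    with open(path, "w") as fh:
        fh.write("window_low\twindow_high\tcount\ttotal\tpercent\n")
        for (lo, hi), c, pct in zip(
            spectrum.window_edges, spectrum.window_counts, spectrum.window_percents()
        ):
            fh.write(f"{lo}\t{hi}\t{c}\t{spectrum.total_sites}\t{pct}\n")
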