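"""Generators for synthetic inputs with the structure each stage assumes.

Every generator is a pure function of its config (seed included), so
identical configs give identical outputs.  The generators emulate:

* allele-depth draws at heterozygous sites under ploidy 2/3/4 — per-site
  allelic dosage is drawn from the heterozygous dosage classes
  (1..ploidy-1), total depth is truncated Poisson, and alternate-read
  counts are binomial around the dosage fraction with sequencing error
  folded into the success probability;
* gene families containing an instantaneous duplication younger than
  speciation, with clock-like branch lengths plus lognormal rate noise,
  emitted as orthogroup count records and newick quartet/triplet trees;
* gene orders perturbed by loss, inversion and translocation;
* TE copy-number tables with planted focal-species bursts.

Gene conversion, incomplete lineage sorting and introgression are
deliberately absent from the family generator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_screens import TEFamilyRecord
from .orthogroups import OrthogroupRecord
from .ploidy_spectrum import AlleleDepthSite

DEFAULT_SPECIES = ("Pant", "Pkai", "Pest")
SPECIES_DELIM = "|"


# ---------------------------------------------------------------------------
# allele depths

@dataclass(frozen=True)
class PloidySimConfig:
    """Study conditions for one simulated depth panel.

    Defaults follow the sequencing regime the evidence rests on: a
    single ~60x short-read individual with dosage classes equally
    weighted and a small per-read error rate.
    """

    ploidy: int
    n_sites: int
    seed: int
    mean_coverage: float = 60.0
    dosage_weights: tuple[float, ...] | None = None  # None = equal
    error_rate: float = 0.005
    scaffold: str = "sim1"

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4):
            raise ValueError("ploidy must be 2, 3 or 4")
        n_classes = self.ploidy - 1
        if self.dosage_weights is not None:
            if len(self.dosage_weights) != n_classes:
                raise ValueError(
                    f"need {n_classes} dosage weights for ploidy {self.ploidy}"
                )
            if abs(sum(self.dosage_weights) - 1.0) > 1e-9:
                raise ValueError("dosage weights must sum to 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_sites < 1 or self.mean_coverage <= 0:
            raise ValueError("n_sites and mean_coverage must be positive")


def sim_allele_depths(
    cfg: PloidySimConfig,
) -> tuple[list[AlleleDepthSite], dict]:
    """Simulate heterozygous-site allele depths under a fixed ploidy.

    Per site: dosage class d ~ dosage_weights over 1..ploidy-1; total
    depth ~ Poisson(mean_coverage) truncated to >= 1; alternate reads ~
    Binomial(depth, p) with p = (d/ploidy)(1-e) + (1-d/ploidy)e.
    """
    rng = np.random.default_rng(cfg.seed)
    n_classes = cfg.ploidy - 1
    weights = (
        np.full(n_classes, 1.0 / n_classes)
        if cfg.dosage_weights is None
        else np.asarray(cfg.dosage_weights)
    )
    dosage = rng.choice(np.arange(1, cfg.ploidy), size=cfg.n_sites, p=weights)
    depth = rng.poisson(cfg.mean_coverage, size=cfg.n_sites)
    redraw = depth < 1
    while redraw.any():  # truncation: depth >= 1
        depth[redraw] = rng.poisson(cfg.mean_coverage, size=int(redraw.sum()))
        redraw = depth < 1
    frac = dosage / cfg.ploidy
    p_alt = frac * (1 - cfg.error_rate) + (1 - frac) * cfg.error_rate
    alt = rng.binomial(depth, p_alt)
    sites = [
        AlleleDepthSite(
            scaffold=cfg.scaffold,
            position=i + 1,
            ref_allele="A",
            alt_allele="C",
            depth_ref=int(depth[i] - alt[i]),
            depth_alt=int(alt[i]),
        )
        for i in range(cfg.n_sites)
    ]
    truth = {"ploidy": cfg.ploidy, "dosage": dosage.tolist()}
    return sites, truth


def sim_mosaic_genome(
    scaffold_ploidies: Sequence[tuple[str, int]],
    n_sites_each: int,
    seed: int,
    mean_coverage: float = 60.0,
    error_rate: float = 0.005,
) -> tuple[list[AlleleDepthSite], dict[str, int]]:
    """Blocks of scaffolds simulated at different ploidies (rediploidizing mosaic)."""
    sites: list[AlleleDepthSite] = []
    truth: dict[str, int] = {}
    for i, (scaffold, ploidy) in enumerate(scaffold_ploidies):
        cfg = PloidySimConfig(
            ploidy=ploidy,
            n_sites=n_sites_each,
            seed=seed + 7919 * (i + 1),
            mean_coverage=mean_coverage,
            error_rate=error_rate,
            scaffold=scaffold,
        )
        block, _ = sim_allele_depths(cfg)
        sites.extend(block)
        truth[scaffold] = ploidy
    return sites, truth


def write_vcf(sites: Sequence[AlleleDepthSite], path: str | os.PathLike,
              sample: str = "SIM") -> None:
    """Write sites as a minimal single-sample VCF 4.2 with GT/AD/GQ/DP."""
    scaffolds = list(dict.fromkeys(s.scaffold for s in sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for sc in scaffolds:
            maxpos = max(s.position for s in sites if s.scaffold == sc)
            fh.write(f"##contig=<ID={sc},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for s in sites:
            dp = s.depth_ref + s.depth_alt
            fh.write(
                f"{s.scaffold}\t{s.position}\t.\t{s.ref_allele}\t{s.alt_allele}"
                f"\t100\tPASS\t.\tGT:AD:DP:GQ\t0/1:{s.depth_ref},{s.depth_alt}:{dp}:99\n"
            )


# ---------------------------------------------------------------------------
# gene families

@dataclass(frozen=True)
class FamilySimConfig:
    """Post-WGD gene-family scenario for three species.

    The tree is ((focal, sister), outgroup): the focal/sister split at
    ``t_split_focal``, the outgroup split at ``t_split_outer``, and the
    WGD on the focal terminal branch at ``t_wgd`` < ``t_split_focal``.
    Defaults mirror the inferred history: with clock_rate such that twice
    the WGD age is ~0.007 substitutions/site and twice the focal/sister
    split ~0.033, retention of WGD duplicates at 0.4 and a 1% background
    duplication rate.
    """

    n_families: int
    seed: int
    t_wgd: float = 0.7
    t_split_focal: float = 3.3
    t_split_outer: float = 3.6
    clock_rate: float = 0.005
    wgd_retention: float = 0.4
    background_dup_rate: float = 0.01
    loss_after_wgd: float = 0.0
    branch_noise_cv: float = 0.2
    species: tuple[str, str, str] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if not (0.0 < self.t_wgd < self.t_split_focal < self.t_split_outer):
            raise ValueError("need 0 < t_wgd < t_split_focal < t_split_outer")
        for name in ("wgd_retention", "background_dup_rate", "loss_after_wgd",
                     "branch_noise_cv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.clock_rate <= 0 or self.n_families < 1:
            raise ValueError("clock_rate and n_families must be positive")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def sim_gene_families(
    cfg: FamilySimConfig,
) -> tuple[list[OrthogroupRecord], list[tuple[str, str]], dict]:
    """Simulate orthogroup records and newick gene trees post-WGD.

    Per family: the focal lineage retains a WGD duplicate with
    probability ``wgd_retention`` (then loses one copy again with
    probability ``loss_after_wgd``); each terminal lineage independently
    gains a background duplicate with probability
    ``background_dup_rate``, at a uniform random time on its branch.
    Branch lengths are clock_rate x time span x lognormal noise.  Emits
    (og_id, newick) pairs for 2:1:1 / 1:2:1 / 1:1:2 quartets and 1:1:1
    triplets; families with >2 copies in a species get counts only.
    """
    rng = np.random.default_rng(cfg.seed)
    focal, sister, outer = cfg.species
    mu = cfg.clock_rate
    records: list[OrthogroupRecord] = []
    trees: list[tuple[str, str]] = []
    truth: dict = {"classes": {}, "dup_times": {}}

    for i in range(cfg.n_families):
        og = f"OG{i:07d}"
        wgd = rng.random() < cfg.wgd_retention
        if wgd and rng.random() < cfg.loss_after_wgd:
            wgd = False
        # background duplication per terminal lineage, uniform on the branch
        terminal_span = {focal: cfg.t_split_focal, sister: cfg.t_split_focal,
                         outer: cfg.t_split_outer}
        bg_dup = {
            sp: (rng.random() < cfg.background_dup_rate) for sp in cfg.species
        }
        bg_time = {sp: rng.uniform(0.0, terminal_span[sp]) for sp in cfg.species}

        counts = {sp: 1 for sp in cfg.species}
        if wgd:
            counts[focal] += 1
        for sp in cfg.species:
            if bg_dup[sp]:
                counts[sp] += 1
        records.append(OrthogroupRecord(og_id=og, counts=dict(counts)))

        dup_sp = [sp for sp in cfg.species if counts[sp] == 2]
        n = lambda: float(_lognormal_noise(rng, cfg.branch_noise_cv, 1)[0])

        if all(c == 1 for c in counts.values()):
            cls = "1:1:1"
            newick = (
                f"(({focal}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_focal * n():.8f},"
                f"{sister}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_focal * n():.8f})"
                f":{mu * (cfg.t_split_outer - cfg.t_split_focal) * n():.8f},"
                f"{outer}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_outer * n():.8f});"
            )
            trees.append((og, newick))
        elif len(dup_sp) == 1 and max(counts.values()) == 2:
            sp = dup_sp[0]
            td = cfg.t_wgd if (sp == focal and wgd) else bg_time[sp]
            truth["dup_times"][og] = td
            a = f"{sp}{SPECIES_DELIM}{og}_1:{mu * td * n():.8f}"
            b = f"{sp}{SPECIES_DELIM}{og}_2:{mu * td * n():.8f}"
            cherry = f"({a},{b})"
            if sp in (focal, sister):
                single_in = sister if sp == focal else focal
                newick = (
                    f"(({cherry}:{mu * (cfg.t_split_focal - td) * n():.8f},"
                    f"{single_in}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_focal * n():.8f})"
                    f":{mu * (cfg.t_split_outer - cfg.t_split_focal) * n():.8f},"
                    f"{outer}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_outer * n():.8f});"
                )
            else:  # outgroup-specific duplicate
                newick = (
                    f"(({focal}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_focal * n():.8f},"
                    f"{sister}{SPECIES_DELIM}{og}_1:{mu * cfg.t_split_focal * n():.8f})"
                    f":{mu * (cfg.t_split_outer - cfg.t_split_focal) * n():.8f},"
                    f"{cherry}:{mu * (cfg.t_split_outer - td) * n():.8f});"
                )
            order = {focal: 0, sister: 1, outer: 2}
            pattern = [1, 1, 1]
            pattern[order[sp]] = 2
            cls = ":".join(map(str, pattern))
            trees.append((og, newick))
        else:
            cls = ":".join(
                "multi" if counts[sp] > 2 else str(counts[sp]) for sp in cfg.species
            )
        truth["classes"][og] = cls
    return records, trees, truth


def write_trees(trees: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    """One newick tree per line."""
    with open(path, "w") as fh:
        for _, newick in trees:
            fh.write(newick + "\n")


def write_genecount_table(
    records: Sequence[OrthogroupRecord], path: str | os.PathLike,
    species: Sequence[str] = DEFAULT_SPECIES,
) -> None:
    """OrthoFinder GeneCount-dialect TSV (with a Total column)."""
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\tTotal\n")
        for r in records:
            counts = [r.counts.get(sp, 0) for sp in species]
            fh.write(r.og_id + "\t" + "\t".join(map(str, counts))
                     + f"\t{sum(counts)}\n")


# ---------------------------------------------------------------------------
# gene orders

@dataclass(frozen=True)
class SyntenySimConfig:
    n_genes: int
    seed: int
    n_assemblies: int = 3
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("inversion_rate", "translocation_rate", "loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 2 or self.n_assemblies < 2:
            raise ValueError("need >= 2 genes and >= 2 assemblies")


def sim_synteny(cfg: SyntenySimConfig) -> tuple[pd.DataFrame, dict]:
    """Derive rearranged assemblies from a common ancestral gene order.

    The ancestor carries genes og0..og{n-1} in order on one scaffold; the
    first assembly ("reference") keeps it intact, each derived assembly
    applies per-gene loss, random-span inversions (expected
    n_genes * inversion_rate events, spans of 2-8 genes) and per-gene
    translocations to a second scaffold.  Returns a gene-position table
    (assembly, scaffold, start, og_id, copy_tag) and a truth record of
    every applied event.
    """
    rng = np.random.default_rng(cfg.seed)
    ogs = [f"og{i:05d}" for i in range(cfg.n_genes)]
    assemblies = ["reference"] + [f"asm{i}" for i in range(1, cfg.n_assemblies)]
    rows = []
    truth: dict = {a: [] for a in assemblies}
    for assembly in assemblies:
        order = list(ogs)
        translocated: list[str] = []
        if assembly != "reference":
            keep = rng.random(len(order)) >= cfg.loss_rate
            lost = [og for og, k in zip(order, keep) if not k]
            order = [og for og, k in zip(order, keep) if k]
            truth[assembly].extend(("loss", og) for og in lost)
            n_inv = rng.binomial(cfg.n_genes, cfg.inversion_rate)
            for _ in range(n_inv):
                if len(order) < 3:
                    break
                span = int(rng.integers(2, 9))
                start = int(rng.integers(0, max(1, len(order) - span)))
                order[start:start + span] = order[start:start + span][::-1]
                truth[assembly].append(("inversion", start, span))
            moved_mask = rng.random(len(order)) < cfg.translocation_rate
            translocated = [og for og, m in zip(order, moved_mask) if m]
            order = [og for og, m in zip(order, moved_mask) if not m]
            truth[assembly].extend(("translocation", og) for og in translocated)
        for pos, og in enumerate(order):
            rows.append((assembly, "scf1", 1000 * (pos + 1), og, ""))
        for pos, og in enumerate(translocated):
            rows.append((assembly, "scf2", 1000 * (pos + 1), og, ""))
    table = pd.DataFrame(
        rows, columns=["assembly", "scaffold", "start", "og_id", "copy_tag"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# TE copy tables

def sim_te_table(
    n_families: int,
    burst_families: int,
    burst_scale: float,
    seed: int,
    species: Sequence[str] = DEFAULT_SPECIES,
    min_copy_diff: float = 100.0,
) -> tuple[list[TEFamilyRecord], dict]:
    """TE copy-number table with planted focal-species bursts.

    Baseline copy numbers are lognormal and strongly correlated across
    species (shared family size times small species-specific noise).
    Each planted burst multiplies the focal species' copies by
    ``burst_scale`` and adds ``min_copy_diff`` so it clears the default
    burst thresholds by construction.
    """
    if burst_families > n_families:
        raise ValueError("burst_families cannot exceed n_families")
    rng = np.random.default_rng(seed)
    focal = species[0]
    base = rng.lognormal(mean=np.log(15.0), sigma=1.0, size=n_families)
    burst_idx = set(rng.choice(n_families, size=burst_families, replace=False).tolist())
    records = []
    for i in range(n_families):
        copies = {
            sp: float(base[i] * rng.lognormal(0.0, 0.15)) for sp in species
        }
        if i in burst_idx:
            copies[focal] = copies[focal] * burst_scale + min_copy_diff
        records.append(TEFamilyRecord(family=f"fam{i:05d}", copies=copies))
    truth = {"burst_families": sorted(f"fam{i:05d}" for i in burst_idx)}
    return records, truth


def write_te_table(
    records: Sequence[TEFamilyRecord], path: str | os.PathLike,
    species: Sequence[str] = DEFAULT_SPECIES,
) -> None:
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(species) + "\n")
        for r in records:
            fh.write(
                r.family + "\t"
                + "\t".join(f"{r.copies[sp]:.3f}" for sp in species) + "\n"
            )


def read_te_table(path: str | os.PathLike) -> list[TEFamilyRecord]:
    df = pd.read_csv(path, sep="\t")
    species = list(df.columns[1:])
    return [
        TEFamilyRecord(
            family=str(row[df.columns[0]]),
            copies={sp: float(row[sp]) for sp in species},
        )
        for _, row in df.iterrows()
    ]
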