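"""Derived summary arithmetic and pipeline orchestration.

The individual evidence stages produce counts and distributions; this
module renders the derived numbers (percentages, percent increases, fold
ratios — all half-up rounded through one routine) and runs requested
stages in dependency order into a single machine-readable evidence
report with a provenance block.
"""

from __future__ import annotations

import json
import logging
import os
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

from ._rounding import round_half_up

logger = logging.getLogger(__name__)


def percent_of(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total, half-up rounded. Exact decimal arithmetic."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total or count < 0:
        raise ValueError("need 0 <= count <= total")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(val)


def percent_increase(a: float, b: float, decimals: int = 1) -> float:
    """100*(a-b)/b, half-up rounded."""
    if b <= 0:
        raise ValueError("baseline must be positive")
    return round_half_up(100.0 * (a - b) / b, decimals)


def fold_ratio(a: float, b: float, decimals: int = 1) -> float:
    """a/b, half-up rounded."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(a / b, decimals)


def run_pipeline(config: dict[str, Any] | str | os.PathLike,
                 out_dir: str | os.PathLike | None = None) -> dict[str, Any]:
    """Run the stages named in a config and assemble an evidence report.

    ``config`` is a dict or a YAML file with any of the sections below;
    stages run independently, and a stage that errors is recorded in the
    report under ``failed`` rather than aborting the rest.

    Sections:
      ``spectrum``:   {vcf, min_depth, min_gq, windows}
      ``ploidy``:     {vcf, top_n, min_sites, freq_min, freq_max, seed}
      ``orthogroups``: {counts, focal, others}
      ``divergence``: {trees, species_delim, duplicated_species}
      ``synteny``:    {positions, reference, window}
      ``te_burst``:   {copies, focal, others, min_copy_diff, min_fold}
      ``simulate``:   {seed, out_dir} — mini scenario generating inputs
                      for every stage above into ``out_dir`` first.
    """
    import yaml

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not config:
        raise ValueError("config names no stages")

    report: dict[str, Any] = {
        "provenance": {"config": _jsonable(config), "package": "wgdscope"},
        "failed": {},
    }

    if "simulate" in config:
        sim = dict(config["simulate"])
        sim_dir = sim.pop("out_dir", out_dir or ".")
        generated = _run_mini_scenario(seed=int(sim.get("seed", 0)), out_dir=sim_dir)
        for stage, inputs in generated.items():
            config.setdefault(stage, {}).update(
                {k: v for k, v in inputs.items() if k not in config.get(stage, {})}
            )

    for stage in ("spectrum", "ploidy", "orthogroups", "divergence",
                  "synteny", "te_burst"):
        if stage not in config:
            continue
        try:
            report[stage] = _STAGES[stage](dict(config[stage]))
        except Exception as exc:  # collected, not propagated
            logger.exception("stage %s failed", stage)
            report["failed"][stage] = f"{type(exc).__name__}: {exc}"

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _stage_spectrum(opts: dict) -> dict:
    from . import ploidy_spectrum as ps

    sites = ps.load_het_sites(
        opts["vcf"],
        min_total_depth=int(opts.get("min_depth", 10)),
        min_genotype_quality=int(opts.get("min_gq", 20)),
    )
    windows = opts.get("windows", ps.DEFAULT_WINDOWS)
    spec = ps.bin_spectrum(sites, windows)
    return {
        "n_sites": spec.total_sites,
        "windows": [
            {"low": lo, "high": hi, "count": c, "percent": pct}
            for (lo, hi), c, pct in zip(
                spec.window_edges, spec.window_counts, spec.window_percents()
            )
        ],
    }


def _stage_ploidy(opts: dict) -> dict:
    from . import ploidy_model as pm
    from . import ploidy_spectrum as ps

    sites = ps.load_het_sites(
        opts["vcf"],
        min_total_depth=int(opts.get("min_depth", 10)),
        min_genotype_quality=int(opts.get("min_gq", 20)),
    )
    seed = int(opts.get("seed", 0))
    freqs = pm.extract_base_freqs(
        sites,
        min_f=float(opts.get("freq_min", 0.1)),
        max_f=float(opts.get("freq_max", 0.9)),
    )
    fit = pm.classify_ploidy(freqs, seed=seed)
    table = pm.per_scaffold_classification(
        sites,
        top_n=int(opts.get("top_n", 100)),
        min_sites=int(opts.get("min_sites", 500)),
        seed=seed,
    )
    return {
        "genome_wide": {
            "best_model": fit.best_model,
            "inv_delta": fit.inv_delta,
            "n_sites": fit.n_sites,
        },
        "per_scaffold": table.to_dict(orient="records"),
    }


def _stage_orthogroups(opts: dict) -> dict:
    from . import orthogroups as og

    records = og.read_genecount_table(opts["counts"])
    focal = opts["focal"]
    others = tuple(opts["others"])
    order = (focal, *others)
    patterns = og.count_patterns(records, order)
    enrich = og.duplication_enrichment(records, focal, others)
    expanded = og.expanded_filter(records, focal, others)
    return {
        "n_orthogroups": len(records),
        "patterns": patterns.to_dict(orient="records"),
        "enrichment": enrich,
        "expanded_og_ids": expanded,
    }


def _stage_divergence(opts: dict) -> dict:
    from . import divergence as dv

    delim = opts.get("species_delim", "|")
    trees = dv.read_trees(opts["trees"], species_delim=delim)
    dup_sp = opts.get("duplicated_species")
    paralog, ortholog = [], []
    for tree in trees:
        n_leaves = sum(1 for _ in tree.leaf_node_iter())
        if n_leaves != 4:
            continue
        summary = dv.quartet_summary(tree, species_delim=delim)
        if dup_sp is not None and summary.duplicated_species != dup_sp:
            continue
        paralog.append(summary.paralog_div)
        ortholog.extend(summary.div_to_other.values())
    out: dict = {"n_quartets": len(paralog)}
    if paralog:
        s = dv.summarize_distances(paralog)
        out["paralog"] = {"median": s.median, "ci_low": s.ci_low,
                          "ci_high": s.ci_high, "n": s.n}
        if len(paralog) >= 10:
            out["paralog"]["peak"] = dv.kde_peak(paralog)
    if ortholog:
        s = dv.summarize_distances(ortholog)
        out["ortholog"] = {"median": s.median, "ci_low": s.ci_low,
                           "ci_high": s.ci_high, "n": s.n}
        if len(ortholog) >= 10:
            out["ortholog"]["peak"] = dv.kde_peak(ortholog)
    return out


def _stage_synteny(opts: dict) -> dict:
    import pandas as pd

    from . import synteny as sy

    positions = opts["positions"]
    if not isinstance(positions, pd.DataFrame):
        positions = pd.read_csv(positions, sep="\t")
    orders = sy.build_gene_orders(positions)
    reference = opts.get("reference", "reference")
    window = int(opts.get("window", 5))
    anchors = opts.get("anchors")
    if anchors is None:
        anchors = sorted({g.og_id for g in orders if g.assembly == reference})
    calls = [
        sy.conserved_microsynteny(a, orders, window=window,
                                  reference_assembly=reference)
        for a in anchors
    ]
    fractions = sy.synteny_fractions(calls)
    return {
        "fractions": {
            cls: {"conserved": c, "total": t, "percent": p}
            for cls, (c, t, p) in fractions.items()
        },
        "n_anchors": len(calls),
    }


def _stage_te_burst(opts: dict) -> dict:
    from . import annotation_screens as ann
    from . import synthetic_data as syn

    records = opts["copies"]
    if isinstance(records, (str, os.PathLike)):
        records = syn.read_te_table(records)
    focal = opts["focal"]
    others = list(opts["others"])
    min_diff = float(opts.get("min_copy_diff", 100.0))
    min_fold = float(opts.get("min_fold", 5.0))
    per_pair = {
        other: ann.te_burst_filter(records, focal, other, min_diff, min_fold)
        for other in others
    }
    return {
        "per_comparison": per_pair,
        "common": ann.burst_intersection(*per_pair.values()),
    }


def _run_mini_scenario(seed: int, out_dir: str | os.PathLike) -> dict:
    """Generate a small end-to-end scenario and return per-stage inputs."""
    from . import synthetic_data as syn

    os.makedirs(out_dir, exist_ok=True)
    scaffolds = [(f"scf{i:02d}", 4) for i in range(7)]
    scaffolds += [("scf07", 2), ("scf08", 2), ("scf09", 3)]
    sites, _ = syn.sim_mosaic_genome(scaffolds, n_sites_each=2000, seed=seed)
    vcf_path = os.path.join(out_dir, "sim.vcf")
    syn.write_vcf(sites, vcf_path)

    fam_cfg = syn.FamilySimConfig(n_families=2000, seed=seed + 1)
    records, trees, _ = syn.sim_gene_families(fam_cfg)
    counts_path = os.path.join(out_dir, "genecounts.tsv")
    trees_path = os.path.join(out_dir, "trees.nwk")
    syn.write_genecount_table(records, counts_path, species=fam_cfg.species)
    syn.write_trees(trees, trees_path)

    syn_cfg = syn.SyntenySimConfig(
        n_genes=300, seed=seed + 2, n_assemblies=3,
        inversion_rate=0.01, translocation_rate=0.005, loss_rate=0.02,
    )
    positions, _ = syn.sim_synteny(syn_cfg)
    pos_path = os.path.join(out_dir, "positions.tsv")
    positions.to_csv(pos_path, sep="\t", index=False)

    te_records, _ = syn.sim_te_table(
        n_families=500, burst_families=20, burst_scale=40.0, seed=seed + 3
    )
    te_path = os.path.join(out_dir, "te_copies.tsv")
    syn.write_te_table(te_records, te_path)

    focal, o1, o2 = syn.DEFAULT_SPECIES
    return {
        "spectrum": {"vcf": vcf_path},
        "ploidy": {"vcf": vcf_path, "seed": seed, "top_n": 10, "min_sites": 500},
        "orthogroups": {"counts": counts_path, "focal": focal, "others": [o1, o2]},
        "divergence": {"trees": trees_path, "duplicated_species": focal},
        "synteny": {"positions": pos_path, "reference": "reference"},
        "te_burst": {"copies": te_path, "focal": focal, "others": [o1, o2]},
    }


_STAGES = {
    "spectrum": _stage_spectrum,
    "ploidy": _stage_ploidy,
    "orthogroups": _stage_orthogroups,
    "divergence": _stage_divergence,
    "synteny": _stage_synteny,
    "te_burst": _stage_te_burst,
}
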