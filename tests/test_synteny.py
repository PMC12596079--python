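import numpy as np
import pandas as pd
import pytest

from wgdscope.synteny import (
    SyntenyGene,
    build_gene_orders,
    conserved_microsynteny,
    synteny_fractions,
)
from wgdscope.synthetic_data import SyntenySimConfig, sim_synteny


def positions_frame(rows):
    return pd.DataFrame(
        rows, columns=["assembly", "scaffold", "start", "og_id", "copy_tag"]
    )


class TestBuildGeneOrders:
    def test_ordinals_follow_coordinates(self):
        df = positions_frame(
            [("a", "s", 100, "g1", ""), ("a", "s", 500, "g2", ""),
             ("a", "s", 900, "g3", "")]
        )
        genes = build_gene_orders(df)
        assert [(g.og_id, g.ordinal) for g in genes] == [
            ("g1", 0), ("g2", 1), ("g3", 2)
        ]

    def test_row_order_invariance(self):
        rows = [("a", "s", 900, "g3", ""), ("a", "s", 100, "g1", ""),
                ("a", "s", 500, "g2", "")]
        shuffled = build_gene_orders(positions_frame(rows))
        ordered = build_gene_orders(positions_frame(sorted(rows)))
        assert shuffled == ordered

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(23)
        starts = rng.choice(100_000, size=50, replace=False)
        rows = [("a", "s", int(s), f"g{i}", "") for i, s in enumerate(starts)]
        genes = build_gene_orders(positions_frame(rows))
        oracle = [
            f"g{i}" for i, _ in sorted(enumerate(starts), key=lambda t: t[1])
        ]
        assert [g.og_id for g in sorted(genes, key=lambda g: g.ordinal)] == oracle

    def test_ordinals_dense_per_scaffold(self):
        df = positions_frame(
            [("a", "s1", 10, "g1", ""), ("a", "s2", 5, "g2", ""),
             ("a", "s1", 20, "g3", "")]
        )
        genes = build_gene_orders(df)
        by_scaffold = {}
        for g in genes:
            by_scaffold.setdefault(g.scaffold, []).append(g.ordinal)
        for ords in by_scaffold.values():
            assert sorted(ords) == list(range(len(ords)))

    def test_duplicate_rows_fatal(self):
        df = positions_frame(
            [("a", "s", 100, "g1", ""), ("a", "s", 100, "g1", "")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_gene_orders(df)


def identical_orders(n=40, assemblies=("reference", "asm1", "asm2")):
    rows = []
    for asm in assemblies:
        for i in range(n):
            rows.append((asm, "s", 100 * (i + 1), f"g{i:03d}", ""))
    return build_gene_orders(positions_frame(rows))


class TestConservedMicrosynteny:
    def test_identical_orders_conserved_everywhere(self):
        orders = identical_orders()
        for og in (f"g{i:03d}" for i in range(40)):
            call = conserved_microsynteny(og, orders)
            assert call.conserved, call.breaks

    def test_translocated_anchor_breaks(self):
        orders = [g for g in identical_orders() if not
                  (g.assembly == "asm1" and g.og_id == "g020")]
        # re-home g020 on a foreign scaffold in asm1
        orders += [
            SyntenyGene("asm1", "other", i, f"x{i}", "") for i in range(10)
        ]
        orders += [SyntenyGene("asm1", "other", 10, "g020", "")]
        call = conserved_microsynteny("g020", orders)
        assert not call.conserved
        assert ("asm1", "translocated") in call.breaks

    def test_absent_anchor_is_break_not_exception(self):
        orders = [g for g in identical_orders()
                  if not (g.assembly == "asm2" and g.og_id == "g010")]
        call = conserved_microsynteny("g010", orders)
        assert ("asm2", "absent") in call.breaks

    def test_duplicated_anchor_requires_both_copies_to_pass(self):
        orders = identical_orders(assemblies=("reference", "asm1"))
        # second copy of g005 sits isolated on another asm1 scaffold
        orders += [
            SyntenyGene("asm1", "iso", i, f"y{i}", "") for i in range(8)
        ]
        orders += [SyntenyGene("asm1", "iso", 8, "g005", "copyB")]
        call = conserved_microsynteny("g005", orders)
        assert call.cls == "2:1:1"
        assert not call.conserved

    def test_matches_neighborhood_set_oracle_with_inversions(self):
        cfg = SyntenySimConfig(
            n_genes=120, seed=29, n_assemblies=3, inversion_rate=0.03
        )
        table, _ = sim_synteny(cfg)
        orders = build_gene_orders(table)
        window = 5
        by_asm = {}
        for g in orders:
            by_asm.setdefault(g.assembly, {})[g.og_id] = g
        scaffold_orders = {}
        for g in orders:
            scaffold_orders.setdefault((g.assembly, g.scaffold), []).append(g)
        for genes in scaffold_orders.values():
            genes.sort(key=lambda g: g.ordinal)

        def oracle(anchor):
            ref = by_asm["reference"][anchor]
            ref_genes = scaffold_orders[("reference", ref.scaffold)]
            i = ref.ordinal
            left = [g.og_id for g in ref_genes[max(0, i - window):i]]
            right = [g.og_id for g in ref_genes[i + 1:i + 1 + window]]
            for asm in ("asm1", "asm2"):
                if anchor not in by_asm[asm]:
                    return False
                cp = by_asm[asm][anchor]
                span_genes = {
                    g.og_id
                    for g in scaffold_orders[(asm, cp.scaffold)]
                    if abs(g.ordinal - cp.ordinal) <= 2 * window + 1
                    and g.og_id != anchor
                }
                for side in (left, right):
                    if side and sum(og in span_genes for og in side) < len(side) - 1:
                        return False
            return True

        anchors = sorted(by_asm["reference"])[:60]
        for anchor in anchors:
            call = conserved_microsynteny(anchor, orders, window=window)
            assert call.conserved == oracle(anchor), anchor

    def test_conservation_fraction_non_increasing_in_rearrangement_rate(self):
        fractions = []
        for rate in (0.0, 0.01, 0.05, 0.2):
            conserved = total = 0
            for seed in range(10):
                cfg = SyntenySimConfig(
                    n_genes=60, seed=31 + seed, n_assemblies=3,
                    inversion_rate=rate, translocation_rate=rate / 2,
                    loss_rate=rate / 2,
                )
                table, _ = sim_synteny(cfg)
                orders = build_gene_orders(table)
                anchors = sorted(
                    {g.og_id for g in orders if g.assembly == "reference"}
                )[:30]
                for a in anchors:
                    call = conserved_microsynteny(a, orders)
                    conserved += call.conserved
                    total += 1
            fractions.append(conserved / total)
        assert all(
            later <= earlier + 0.02
            for earlier, later in zip(fractions, fractions[1:])
        ), fractions
        assert fractions[0] == 1.0


class TestSyntenyFractions:
    def _call(self, og, cls, conserved):
        from wgdscope.synteny import ConservationCall

        breaks = () if conserved else (("asm1", "rearranged"),)
        return ConservationCall(og_id=og, cls=cls, breaks=breaks)

    def test_zero_conserved_is_zero_percent(self):
        calls = [self._call(f"g{i}", "1:1:1", False) for i in range(5)]
        assert synteny_fractions(calls)["1:1:1"] == (0, 5, 0)

    def test_per_class_tallies_and_integer_percent(self):
        calls = [self._call(f"a{i}", "2:1:1", i < 53) for i in range(57)]
        calls += [self._call(f"b{i}", "1:1:1", i < 45) for i in range(62)]
        out = synteny_fractions(calls)
        assert out["2:1:1"] == (53, 57, 93)
        assert out["1:1:1"] == (45, 62, 73)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            synteny_fractions([])
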