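"""Fisher enrichment of peak sets in DEG promoters, against exact oracles."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfrn.enrichment import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    fisher_pvalue,
    genes_bound,
    run_enrichment,
)
from tfrn.genomic_io import InputError, PeakInterval, PeakSet, PromoterRegion

from oracles import exact_fisher_greater, naive_bh


def prom(gene, start, end, chrom="chr1"):
    return PromoterRegion(gene, chrom, start, end, "+")


class TestGenesBound:
    def test_partial_overlap_binds(self):
        ps = PeakSet("tf", "col", [PeakInterval("chr1", 4990, 5100)])
        assert genes_bound([prom("g", 4000, 5000)], ps) == {"g"}

    def test_half_open_boundary_no_overlap(self):
        ps = PeakSet("tf", "col", [PeakInterval("chr1", 5000, 5100)])
        assert genes_bound([prom("g", 4000, 5000)], ps) == set()

    def test_binarized_over_peak_multiplicity(self):
        ps = PeakSet(
            "tf", "col",
            [PeakInterval("chr1", 4100, 4200), PeakInterval("chr1", 4500, 4600)],
        )
        assert genes_bound([prom("g", 4000, 5000)], ps) == {"g"}

    def test_min_overlap_threshold(self):
        ps = PeakSet("tf", "col", [PeakInterval("chr1", 4995, 5100)])
        assert genes_bound([prom("g", 4000, 5000)], ps, min_overlap_bp=5) == {"g"}
        assert genes_bound([prom("g", 4000, 5000)], ps, min_overlap_bp=6) == set()

    def test_chromosome_dialect_mismatch_warns(self, caplog):
        ps = PeakSet("tf", "col", [PeakInterval("1", 4000, 4200)])
        with caplog.at_level("WARNING"):
            assert genes_bound([prom("g", 4000, 5000, chrom="chr1")], ps) == set()
        assert "chromosome" in caplog.text


class TestContingency:
    def test_set_arithmetic(self):
        universe = {f"g{i}" for i in range(1, 11)}
        t = build_contingency({"g1", "g2", "g3"}, {"g1", "g2", "g4"}, universe)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 6)

    def test_nothing_bound(self):
        universe = {f"g{i}" for i in range(10)}
        t = build_contingency({"g1", "g2"}, set(), universe)
        assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 8)

    def test_deg_equals_universe_degenerate(self):
        universe = {"g1", "g2"}
        t = build_contingency(universe, {"g1"}, universe)
        assert (t.c, t.d) == (0, 0)
        assert 0 < fisher_pvalue(t) <= 1

    def test_empty_universe_errors(self):
        with pytest.raises(InputError):
            build_contingency({"g"}, set(), set())


class TestFisher:
    def test_known_tail_2_1_1_6(self):
        # P(X>=2), X~Hypergeom(N=10,K=3,n=3) = (C(3,2)C(7,1)+C(3,3))/C(10,3)
        expected = Fraction(21 + 1, 120)
        assert exact_fisher_greater(2, 1, 1, 6) == expected
        assert fisher_pvalue(ContingencyTable(2, 1, 1, 6)) == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_zero_a_gives_one(self):
        assert fisher_pvalue(ContingencyTable(0, 5, 3, 7)) == 1.0

    def test_single_term_tail(self):
        # (3,0,0,7): only the fully-bound configuration, p = 1/C(10,3)
        assert exact_fisher_greater(3, 0, 0, 7) == Fraction(1, 120)
        assert fisher_pvalue(ContingencyTable(3, 0, 0, 7)) == pytest.approx(
            1 / 120, rel=1e-12
        )

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12),
            st.integers(0, 12), st.integers(0, 12),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exact_rational_oracle(self, cells):
        a, b, c, d = cells
        got = fisher_pvalue(ContingencyTable(a, b, c, d))
        want = float(exact_fisher_greater(a, b, c, d))
        assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_monotone_in_new_deg_overlap(self):
        """Binding one more DEG promoter (a+1, b-1, holding the rest) never
        increases the enrichment p-value."""
        for a, b, c, d in [(0, 5, 2, 13), (3, 4, 1, 12), (5, 1, 0, 14)]:
            p0 = fisher_pvalue(ContingencyTable(a, b, c, d))
            p1 = fisher_pvalue(ContingencyTable(a + 1, b - 1, c, d))
            assert p1 <= p0 + 1e-15


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.5], [0.5]),
            ([0.03, 0.01], [0.03, 0.02]),  # input order preserved
            ([], []),
        ],
    )
    def test_hand_worked_step_up(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_naive_step_up(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(naive_bh(pvals), rel=1e-12, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestRunEnrichment:
    def _tiny_inputs(self):
        promoters = [prom(f"g{i}", i * 3000, i * 3000 + 1000) for i in range(20)]
        import pandas as pd

        from tfrn.genomic_io import DEGTable

        degs = DEGTable(pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)],
             "direction": ["up"] * 4 + ["down"] * 4}
        ))
        # tf_a binds all four up-DEG promoters; tf_b binds one neutral gene
        peaks_a = [PeakInterval("chr1", i * 3000 + 100, i * 3000 + 300) for i in range(4)]
        peaks_b = [PeakInterval("chr1", 15 * 3000 + 100, 15 * 3000 + 300)]
        sets = [PeakSet("tf_a", "col", peaks_a), PeakSet("tf_b", "col", peaks_b)]
        return promoters, sets, degs

    def test_cardinality_and_pooling(self):
        promoters, sets, degs = self._tiny_inputs()
        records = run_enrichment(promoters, sets, degs, alpha=0.05)
        assert len(records) == 4  # 2 peak sets x 2 directions
        by_key = {(r.tf_gene_id, r.deg_direction): r for r in records}
        # tf_a binds every up DEG and nothing else: strongly enriched "up"
        assert by_key[("tf_a", "up")].enriched
        assert not by_key[("tf_b", "up")].enriched
        assert not by_key[("tf_a", "down")].enriched

    def test_alpha_one_marks_everything(self):
        promoters, sets, degs = self._tiny_inputs()
        records = run_enrichment(promoters, sets, degs, alpha=1.0)
        assert all(r.enriched for r in records)

    def test_mixed_libraries_rejected(self):
        promoters, sets, degs = self._tiny_inputs()
        sets[1] = PeakSet("tf_b", "colamp", sets[1].peaks)
        with pytest.raises(InputError, match="librar"):
            run_enrichment(promoters, sets, degs)

    def test_label_invariance(self):
        """Permuting promoter and peak order changes nothing."""
        promoters, sets, degs = self._tiny_inputs()
        base = run_enrichment(promoters, sets, degs, alpha=0.05)
        flipped = run_enrichment(
            list(reversed(promoters)),
            [PeakSet(s.tf_gene_id, s.library_label, list(reversed(s.peaks)))
             for s in reversed(sets)],
            degs, alpha=0.05,
        )
        assert [
            (r.tf_gene_id, r.deg_direction, r.table, r.p_value, r.q_value)
            for r in base
        ] == [
            (r.tf_gene_id, r.deg_direction, r.table, r.p_value, r.q_value)
            for r in flipped
        ]
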