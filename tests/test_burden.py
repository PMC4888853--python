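import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from helpers import make_cohort, make_family, make_variant

from pedburden.burden import (
    ContingencyTable,
    QualifyingRule,
    bh_adjust,
    build_table,
    carrier_prevalence,
    fisher_exact_two_sided,
    rank_genes,
    run_burden,
    select_qualifying,
    GeneBurdenResult,
)
from pedburden.simulate import SimulationConfig, simulate_cohort
from pedburden.types import AnnotationRecord, DataValidationError, PanelAF

cells = st.integers(min_value=0, max_value=50)


class TestQualifyingRule:
    def _cohort(self, sift, polyphen, maf):
        v = make_variant(gene="G1")
        ann = {v.key: AnnotationRecord(variant_key=v.key,
                                       consequence="missense",
                                       sift=sift, polyphen=polyphen)}
        panel = PanelAF({v.key: {"finnish": maf}})
        return make_cohort([v], {"A": [1]}, annotations=ann, panel=panel)

    def test_rare_deleterious_qualifies(self):
        cohort = self._cohort("D", "D", 0.01)
        assert len(select_qualifying("G1", cohort)) == 1

    def test_possibly_damaging_qualifies(self):
        cohort = self._cohort("D", "P", 0.01)
        assert len(select_qualifying("G1", cohort)) == 1

    def test_sift_tolerated_excluded(self):
        cohort = self._cohort("T", "D", 0.01)
        assert select_qualifying("G1", cohort) == []

    def test_common_excluded(self):
        cohort = self._cohort("D", "D", 0.03)
        assert select_qualifying("G1", cohort) == []


def _proband_cohort(n_probands, het_carriers, gene="G1", ac=50, an=10000):
    v = make_variant(gene=gene)
    peds, dosages = [], {}
    for i in range(n_probands):
        sid = f"p{i}"
        peds.append(make_family(f"F{i}", [(sid, None, None, "male",
                                           "affected", True)]))
        dosages[sid] = [1 if i < het_carriers else 0]
    ann = {v.key: AnnotationRecord(variant_key=v.key,
                                   consequence="missense",
                                   sift="D", polyphen="D")}
    panel = PanelAF({v.key: {"finnish": 0.005}},
                    ref_counts={v.key: (ac, an)})
    return make_cohort([v], dosages, pedigrees=peds, annotations=ann,
                       panel=panel)


class TestBuildTable:
    def test_allele_counting(self):
        cohort = _proband_cohort(10, het_carriers=4)
        t = build_table("G1", cohort)
        assert (t.a, t.b) == (4, 16)
        assert (t.c, t.d) == (50, 9950)

    def test_no_qualifying_variants(self):
        cohort = _proband_cohort(10, het_carriers=4)
        cohort.annotations = {
            k: AnnotationRecord(variant_key=k, consequence="missense",
                                sift="T", polyphen="B")
            for k in cohort.annotations}
        t = build_table("G1", cohort)
        assert (t.a, t.b, t.c) == (0, 20, 0)

    def test_no_probands_is_an_error(self):
        v = make_variant()
        cohort = make_cohort([v], {"A": [1]})
        with pytest.raises(DataValidationError, match="proband"):
            build_table("GENE1", cohort)

    def test_matches_brute_force_recount_on_simulated_cohort(
            self, small_cohort):
        """Independent recount: sum proband dosages straight off the
        genotype matrix for the qualifying keys."""
        gene = small_cohort.truth["causal_gene"]
        qualifying = select_qualifying(gene, small_cohort)
        t = build_table(gene, small_cohort)
        gm = small_cohort.genotypes
        probands = [m.sample_id for ped in small_cohort.pedigrees
                    for m in ped.members.values() if m.is_proband]
        expect_a = sum(
            max(int(gm.dosages[gm.sample_idx(p), gm.variant_idx(k)]), 0)
            for p in probands for k in qualifying)
        assert t.a == expect_a
        assert t.b == 2 * len(probands) - expect_a


class TestFisherExact:
    def test_empty_qualifying_margin_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 5, 0, 9)) == 1.0

    def test_hand_enumerated_table(self):
        # margins (4,4)/(4,4): p = (1+16+16+1)/70
        p = fisher_exact_two_sided(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(DataValidationError):
            ContingencyTable(-1, 1, 1, 1)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 51, 4))
            mine = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, abs=1e-10)

    @settings(deadline=None, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_transpose_invariance_and_range(self, a, b, c, d):
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        pt = fisher_exact_two_sided(ContingencyTable(a, c, b, d))
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(pt, rel=1e-9)

    def test_large_reference_margins(self):
        p = fisher_exact_two_sided(ContingencyTable(19, 21, 200, 9800))
        ref = fisher_exact([[19, 21], [200, 9800]])[1]
        assert p == pytest.approx(ref, rel=1e-6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_worked_vector(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_constant_vector_unchanged(self):
        assert bh_adjust([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            mine = np.array(bh_adjust(p.tolist()))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(mine - ref)) < 1e-12

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_monotone_and_bounded(self, ps):
        adj = bh_adjust(ps)
        assert all(0 <= a <= 1 for a in adj)
        # one ulp of slack: G*p/G need not round-trip exactly
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        order = np.argsort(ps)
        sorted_adj = [adj[i] for i in order]
        assert all(x <= y for x, y in zip(sorted_adj, sorted_adj[1:]))


class TestRankingAndPrevalence:
    def test_deterministic_lexicographic_tie_break(self):
        t = ContingencyTable(1, 1, 1, 1)
        res = [GeneBurdenResult(gene=g, table=t, p_raw=0.5, p_adj=0.5)
               for g in ["B", "A", "C"]]
        ranked = rank_genes(res)
        assert [r.gene for r in ranked] == ["A", "B", "C"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_planted_gene_ranks_first(self, small_cohort):
        results = run_burden(small_cohort, small_cohort.genes)
        assert results[0].gene == small_cohort.truth["causal_gene"]
        assert results[0].significant

    def test_adjusted_at_least_raw(self, small_cohort):
        for r in run_burden(small_cohort, small_cohort.genes):
            assert r.p_adj >= r.p_raw - 1e-15

    @pytest.mark.parametrize("counts,n,expected", [
        ((5, 29), 334, 10.2),   # LoF + missense carriers in an HH cohort
        ((0,), 100, 0.0),
        ((100,), 100, 100.0),
        ((1,), 8, 12.5),
    ])
    def test_carrier_prevalence_rounding(self, counts, n, expected):
        assert carrier_prevalence(counts, n) == expected

    def test_prevalence_half_up(self):
        # 0.15% -> 0.2 under half-up rounding
        assert carrier_prevalence((3,), 2000) == 0.2

    def test_prevalence_count_overflow_rejected(self):
        with pytest.raises(DataValidationError):
            carrier_prevalence((5, 6), 10)
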