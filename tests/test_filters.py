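import itertools

import numpy as np
import pytest

from helpers import make_cohort, make_family, make_variant

from pedburden.filters import (
    FilterConfig,
    consequence_filter,
    control_screen,
    maf_filter,
    multifamily_filter,
    predictor_consensus,
    qc_filter,
    run_cascade,
    segregation_filter,
)
from pedburden.simulate import SimulationConfig, simulate_cohort
from pedburden.types import AnnotationRecord, DataValidationError, PanelAF

CFG = FilterConfig()


class TestQcFilter:
    def test_empty_input(self):
        cohort = make_cohort([], {"A": []})
        assert qc_filter(cohort, set(), CFG) == (set(), {})

    def test_single_low_quality_carrier_removed(self):
        v = make_variant()
        cohort = make_cohort([v], {"A": [1]}, gq={"A": [10.0]},
                             dp={"A": [30.0]})
        survivors, reasons = qc_filter(cohort, {v.key}, CFG)
        assert survivors == set()
        assert "GQ/DP" in reasons[v.key]

    def test_one_good_carrier_suffices(self):
        v = make_variant()
        cohort = make_cohort([v], {"A": [1], "B": [1]},
                             gq={"A": [10.0], "B": [45.0]},
                             dp={"A": [30.0], "B": [30.0]})
        survivors, _ = qc_filter(cohort, {v.key}, CFG)
        assert survivors == {v.key}

    def test_missing_gq_dp_pass(self):
        v = make_variant()
        cohort = make_cohort([v], {"A": [1]})
        survivors, _ = qc_filter(cohort, {v.key}, CFG)
        assert survivors == {v.key}


class TestConsequenceFilter:
    @pytest.mark.parametrize("consequence,kept", [
        ("missense", True), ("nonsense", True), ("splice_site", True),
        ("promoter", True), ("frameshift", True),  # LoF always kept
        ("other", False),
    ])
    def test_classes(self, consequence, kept):
        v = make_variant()
        ann = {v.key: AnnotationRecord(variant_key=v.key,
                                       consequence=consequence)}
        cohort = make_cohort([v], {"A": [1]}, annotations=ann)
        survivors, _ = consequence_filter(cohort, {v.key}, CFG)
        assert (v.key in survivors) == kept

    def test_unannotated_variant_is_an_error(self):
        v = make_variant()
        cohort = make_cohort([v], {"A": [1]}, annotations={})
        with pytest.raises(DataValidationError, match=v.key):
            consequence_filter(cohort, {v.key}, CFG)


class TestMafFilter:
    def test_rare_in_seen_panel_kept(self):
        # a 2.0% Finnish-panel variant passes the 2.5% threshold
        panel = PanelAF({"k": {"finnish": 0.020, "european": 0.007}})
        assert maf_filter({"k"}, panel, CFG)[0] == {"k"}

    def test_not_seen_anywhere_kept(self):
        assert maf_filter({"k"}, PanelAF(), CFG)[0] == {"k"}

    def test_common_in_any_panel_removed(self):
        panel = PanelAF({"k": {"finnish": 0.001, "european": 0.03}})
        survivors, reasons = maf_filter({"k"}, panel, CFG)
        assert survivors == set()
        assert "0.03" in reasons["k"]

    def test_boundary_equal_to_threshold_removed(self):
        panel = PanelAF({"k": {"finnish": 0.025}})
        assert maf_filter({"k"}, panel, CFG)[0] == set()


class TestPredictorConsensus:
    @pytest.mark.parametrize("calls,count,passes", [
        # discovery-variant profiles: (sift, polyphen, lrt, mt, fathmm)
        (("D", "D", "D", "N", "D"), 4, True),   # p.R156L
        (("D", "D", "D", "D", "T"), 4, True),   # p.E161K
        (("D", "P", "N", "D", "T"), 3, True),   # p.E2264G
        (("D", "D", "D", "D", "T"), 4, True),   # p.D2614N
        (("T", "B", "N", "N", "T"), 0, False),  # all tolerated
        (("D", "P", "N", "N", "T"), 2, False),
    ])
    def test_damaging_tool_count(self, calls, count, passes):
        sift, poly, lrt, mt, fathmm = calls
        ann = AnnotationRecord(variant_key="k", consequence="missense",
                               sift=sift, polyphen=poly, lrt=lrt,
                               mutation_taster=mt, fathmm=fathmm)
        assert predictor_consensus(ann, CFG) == (passes, count)


def _segregation_case(phenotypes, carriers):
    """Build a one-variant cohort for a pedigree of unrelated members."""
    v = make_variant()
    members = [(f"s{i}", None, None, "male", ph)
               for i, ph in enumerate(phenotypes)]
    ped = make_family("F1", members)
    dosages = {f"s{i}": [1 if i in carriers else 0]
               for i in range(len(phenotypes))}
    cohort = make_cohort([v], dosages, pedigrees=[ped])
    return cohort, v.key, ped


class TestSegregationFilter:
    def test_one_affected_noncarrier_tolerated(self):
        # n=4 affected, 3 affected carriers + 1 unaffected carrier: kept
        phen = ["affected"] * 4 + ["unaffected"] * 2
        cohort, key, ped = _segregation_case(phen, carriers={0, 1, 2, 4})
        ok, detail = segregation_filter(cohort, key, ped, CFG)
        assert ok
        assert detail["affected_carriers"] == 3
        assert detail["unaffected_carriers"] == 1

    def test_two_unaffected_carriers_rejected(self):
        phen = ["affected"] * 3 + ["unaffected"] * 2
        cohort, key, ped = _segregation_case(phen, carriers={0, 1, 2, 3, 4})
        ok, _ = segregation_filter(cohort, key, ped, CFG)
        assert not ok

    def test_absent_variant_not_segregating(self):
        phen = ["affected", "unaffected"]
        cohort, key, ped = _segregation_case(phen, carriers=set())
        ok, detail = segregation_filter(cohort, key, ped, CFG)
        assert not ok and detail["reason"] == "absent"

    def test_unknown_phenotype_excluded_from_counts(self):
        phen = ["affected", "affected", "unknown", "unknown", "unknown"]
        cohort, key, ped = _segregation_case(phen, carriers={0, 1, 2, 3, 4})
        ok, detail = segregation_filter(cohort, key, ped, CFG)
        assert ok
        assert detail["unaffected_carriers"] == 0

    @pytest.mark.parametrize("phenotypes", [
        ("affected", "affected", "unaffected"),
        ("affected",) * 4 + ("unaffected",) * 2,
        ("affected", "affected", "affected", "unaffected", "unknown",
         "unaffected"),
        ("affected",) * 2 + ("unaffected",) * 4 + ("unknown",) * 2,
        ("affected",) * 5 + ("unaffected",) * 3,
    ])
    def test_matches_brute_force_rule_over_all_carrier_sets(self, phenotypes):
        """Exhaustive oracle: the filter decision equals direct evaluation
        of "carried by >= n-1 of n affected and by <= 1 unaffected"."""
        m = len(phenotypes)
        for bits in itertools.product([0, 1], repeat=m):
            carriers = {i for i in range(m) if bits[i]}
            cohort, key, ped = _segregation_case(list(phenotypes), carriers)
            got, _ = segregation_filter(cohort, key, ped, CFG)
            aff = [i for i in range(m) if phenotypes[i] == "affected"]
            unaff = [i for i in range(m) if phenotypes[i] == "unaffected"]
            expected = (
                bool(carriers)
                and len(carriers & set(aff)) >= len(aff) - 1
                and len(carriers & set(unaff)) <= 1
            )
            assert got == expected, (phenotypes, carriers)


class TestMultifamilyFilter:
    GENES = {"v1": "G1", "v2": "G1", "v3": "G2"}

    def test_same_variant_two_families_kept(self):
        seg = {"v1": {"A", "B"}, "v3": {"A"}}
        survivors, _ = multifamily_filter(seg, self.GENES, CFG)
        assert "v1" in survivors

    def test_different_variants_same_gene_both_kept(self):
        seg = {"v1": {"A"}, "v2": {"B"}}
        survivors, _ = multifamily_filter(seg, self.GENES, CFG)
        assert survivors == {"v1", "v2"}

    def test_singleton_removed(self):
        seg = {"v3": {"A"}}
        survivors, reasons = multifamily_filter(seg, self.GENES, CFG)
        assert survivors == set() and "v3" in reasons


class TestControlScreen:
    @pytest.mark.parametrize("n_carriers,kept", [(0, True), (1, True),
                                                 (2, False)])
    def test_carrier_thresholds(self, n_carriers, kept):
        v = make_variant()
        controls = [f"c{i}" for i in range(3)]
        dosages = {c: [1 if i < n_carriers else 0]
                   for i, c in enumerate(controls)}
        cohort = make_cohort([v], dosages, controls=controls)
        ok, n = control_screen(cohort, v.key, CFG)
        assert ok == kept and n == n_carriers


class TestCascade:
    def test_empty_cohort(self):
        cohort = make_cohort([], {"A": []})
        candidates, genes, trace = run_cascade(cohort)
        assert candidates == [] and genes == []
        assert all(s.variants_in == 0 for s in trace.stages)

    def test_trace_counts_non_increasing(self, small_cohort):
        _, _, trace = run_cascade(small_cohort)
        for stage in trace.stages:
            assert stage.variants_out <= stage.variants_in
        outs = [s.variants_out for s in trace.stages]
        ins = [s.variants_in for s in trace.stages]
        assert ins[1:] == outs[:-1]

    def test_planted_causal_gene_survives_at_full_penetrance(self):
        sim = simulate_cohort(SimulationConfig(
            seed=21, n_families=10, penetrance=1.0, phenocopy_rate=0.0,
            n_background_genes=20))
        candidates, genes, _ = run_cascade(sim.cohort)
        assert sim.truth["causal_gene"] in genes
        assert set(candidates) & set(sim.truth["causal_variants"])

    def test_gene_allowlist_stage(self, small_cohort):
        causal = small_cohort.truth["causal_gene"]
        config = FilterConfig(gene_allowlist=frozenset({causal}))
        _, genes, trace = run_cascade(small_cohort, config)
        assert genes == [causal] or genes == []
        assert any(s.name == "gene_allowlist" for s in trace.stages)

    def test_per_variant_stage_order_independence(self, small_cohort):
        """QC, consequence, MAF and consensus are per-variant predicates:
        any order of those four stages keeps the same variant set."""
        cohort = small_cohort
        keys = {v.key for v in cohort.variants}
        config = CFG

        def consensus_stage(ks):
            return ({k for k in ks
                     if predictor_consensus(cohort.annotations[k], config)[0]},
                    {})

        stages = [
            lambda ks: qc_filter(cohort, ks, config),
            lambda ks: consequence_filter(cohort, ks, config),
            lambda ks: maf_filter(ks, cohort.panel, config),
            consensus_stage,
        ]
        results = []
        for perm in itertools.permutations(range(4)):
            current = set(keys)
            for i in perm:
                current = stages[i](current)[0]
            results.append(current)
        assert all(r == results[0] for r in results[1:])

    def test_recovery_rate_not_higher_at_reduced_penetrance(self):
        def survival(penetrance, seeds=range(8)):
            hits = 0
            for seed in seeds:
                sim = simulate_cohort(SimulationConfig(
                    seed=100 + seed, penetrance=penetrance,
                    n_families=10, n_background_genes=10))
                _, genes, _ = run_cascade(sim.cohort)
                hits += sim.truth["causal_gene"] in genes
            return hits / 8

        full = survival(1.0)
        reduced = survival(0.6)
        assert full == 1.0
        assert reduced <= full
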