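"""Fisher exact machinery and the gene-centric association battery."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimut import association
from epimut.association import (
    Assoc2x2,
    build_gene_states,
    class_comparison,
    concordance,
    fisher_2x2,
    simultaneity_breakdown,
    stepwise_association,
    term_enrichment,
)
from epimut.inheritance import EpimutationRun
from epimut.model import ValidationError


def run(gene, lineage="C1", direction=1, start=2, end=2, n=1):
    return EpimutationRun(gene, lineage, direction, start, end, n, False)


class TestFisher2x2:
    @pytest.mark.parametrize(
        "table,or_print,p_expect",
        [
            ((75, 2, 912, 16), "0.66", 0.64),
            ((73, 4, 936, 8), "0.16", 9.30e-03),
            ((65, 6, 851, 8), "0.10", 2.96e-04),
        ],
    )
    def test_printed_control_tables(self, table, or_print, p_expect):
        res = fisher_2x2(*table)
        assert f"{res.odds_ratio:.2f}" == or_print
        assert res.p == pytest.approx(p_expect, rel=0.01)

    def test_infinite_odds_ratio(self):
        res = fisher_2x2(5, 0, 10, 10)
        assert res.odds_ratio == math.inf

    def test_zero_odds_ratio(self):
        res = fisher_2x2(0, 5, 10, 0)
        assert res.odds_ratio == 0.0

    def test_undefined_odds_ratio(self):
        # both cross products vanish: no information about the odds
        res = fisher_2x2(0, 5, 0, 0)
        assert math.isnan(res.odds_ratio)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_2x2(0, 0, 0, 0)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(60)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b + c + d == 0:
                continue
            t1 = fisher_2x2(a, b, c, d)
            t2 = fisher_2x2(a, c, b, d)
            assert t1.p == pytest.approx(t2.p, abs=1e-14)
            if not math.isnan(t1.odds_ratio):
                assert t1.odds_ratio == t2.odds_ratio

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            res = fisher_2x2(a, b, c, d)
            _, p_sp = stats.fisher_exact([[a, b], [c, d]])
            assert res.p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)

    def test_exact_fraction_oracle_small_margins(self):
        # exhaustive hypergeometric enumeration with exact rationals
        def oracle(a, b, c, d):
            r1, r2, k = a + b, c + d, a + c
            lo, hi = max(0, k - r2), min(k, r1)
            denom = math.comb(r1 + r2, k)
            p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
            total = Fraction(0)
            for x in range(lo, hi + 1):
                p = Fraction(math.comb(r1, x) * math.comb(r2, k - x), denom)
                if p <= p_obs:
                    total += p
            return float(total)

        rng = np.random.default_rng(62)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_2x2(a, b, c, d).p == pytest.approx(
                oracle(a, b, c, d), abs=1e-12
            )

    def test_conditional_mle_close_to_sample_or(self):
        res = fisher_2x2(75, 2, 912, 16)
        assert res.odds_ratio_cmle == pytest.approx(res.odds_ratio, rel=0.05)


class TestStepwise:
    def make_states(self, coupled=1.0, n_genes=60, seed=0):
        """Genes whose expression change accompanies an sRNA run with
        probability ``coupled``; the remainder get independent runs."""
        rng = np.random.default_rng(seed)
        expr, srna = [], []
        genes = [f"gene{i}" for i in range(n_genes)]
        for g in genes[: n_genes // 2]:
            start = int(rng.choice([2, 4, 6, 8]))
            expr.append(run(g, start=start, end=start + 2, n=2))
            if rng.random() < coupled:
                srna.append(run(g, start=start, end=start, n=1))
            elif rng.random() < 0.2:
                srna.append(run(g, start=16, end=16, n=1))
        states = build_gene_states(expr, {"g22": srna})
        return states, genes

    def test_no_srna_epimutations_gives_nan_association(self):
        states = build_gene_states([run("gene0", n=2, end=4)], {"g22": []})
        tests = stepwise_association(states, "g22", ["gene0", "gene1"])
        assert math.isnan(tests[1].odds_ratio)

    def test_forced_coupling_detected(self):
        states, genes = self.make_states(coupled=1.0)
        tests = stepwise_association(states, "g22", genes)
        assert tests[1].odds_ratio == math.inf or tests[1].odds_ratio > 1
        assert tests[1].p < 0.05

    def test_independence_null_calibrated(self):
        rng = np.random.default_rng(63)
        n_sig = 0
        n_trials = 20
        for trial in range(n_trials):
            genes = [f"g{i}" for i in range(2000)]
            expr = [run(g, start=int(s), end=int(s))
                    for g in genes for s in [rng.choice(range(2, 21, 2))]
                    if rng.random() < 0.05]
            srna = [run(g, start=int(s), end=int(s))
                    for g in genes for s in [rng.choice(range(2, 21, 2))]
                    if rng.random() < 0.05]
            states = build_gene_states(expr, {"g22": srna})
            tests = stepwise_association(states, "g22", genes)
            if tests[1] is not None and tests[1].p < 0.05:
                n_sig += 1
        assert 0 <= n_sig / n_trials <= 0.12

    def test_monotone_in_coupling_strength(self):
        ors = []
        for coupled in (0.0, 0.5, 1.0):
            states, genes = self.make_states(coupled=coupled, n_genes=400, seed=7)
            tests = stepwise_association(states, "g22", genes)
            or_ = tests[1].odds_ratio
            ors.append(math.inf if math.isinf(or_) else or_)
        assert ors[0] <= ors[1] <= ors[2]


class TestConcordance:
    def test_all_matched_means_no_discordant(self):
        expr = [run("g1", direction=1), run("g2", direction=-1)]
        srna = [run("g1", direction=1), run("g2", direction=-1)]
        states = build_gene_states(expr, {"g22": srna})
        table = concordance(states, "g22").set_index("class")
        assert table.loc["discordant", "n_class"] == 0
        assert table.loc["concordant", "n_class"] == 2

    def test_anticorrelated_construction_enriches_discordant(self):
        expr = [run(f"g{i}", direction=-1) for i in range(20)]
        srna = [run(f"g{i}", direction=1) for i in range(20)]
        # a few genes with both change types but at different generations
        expr += [run(f"h{i}", direction=1, start=2, end=2) for i in range(3)]
        srna += [run(f"h{i}", direction=1, start=16, end=16) for i in range(3)]
        states = build_gene_states(expr, {"g22": srna})
        table = concordance(states, "g22").set_index("class")
        assert table.loc["discordant", "odds_ratio"] > 1

    def test_no_simultaneous_pairs_is_an_error(self):
        expr = [run("g1", start=2, end=2)]
        srna = [run("g1", start=10, end=10)]
        states = build_gene_states(expr, {"g22": srna})
        with pytest.raises(ValidationError, match="simultaneous"):
            concordance(states, "g22")


class TestSimultaneityBreakdown:
    def test_single_gene_simultaneous_inherited(self):
        expr = [run("g1", n=2, end=4)]
        srna = [run("g1", n=2, end=4)]
        states = build_gene_states(expr, {"g22": srna})
        table = simultaneity_breakdown(states, "g22")
        row = table[table["expr_inherited"]].iloc[0]
        assert row["simultaneous_inherited_pct"] == 100.0
        assert row["non_simultaneous_pct"] == 0.0

    def test_percentages_partition_to_hundred(self):
        rng = np.random.default_rng(64)
        expr, srna = [], []
        for i in range(100):
            g = f"g{i}"
            expr.append(run(g, n=int(rng.integers(1, 3)), start=4,
                            end=4 + 2 * int(rng.integers(0, 2))))
            start = int(rng.choice([4, 12]))
            srna.append(run(g, n=int(rng.integers(1, 3)), start=start,
                            end=start + 2 * int(rng.integers(0, 2))))
        states = build_gene_states(expr, {"g22": srna})
        table = simultaneity_breakdown(states, "g22")
        for _, row in table.iterrows():
            if row["n_genes"]:
                total = (row["simultaneous_inherited_pct"]
                         + row["simultaneous_non_inherited_pct"]
                         + row["non_simultaneous_pct"])
                assert total == pytest.approx(100.0, abs=1e-9)

    def test_known_proportions_recovered(self):
        expr, srna = [], []
        # 6 simultaneous+inherited, 2 simultaneous transient, 2 non-simultaneous
        for i in range(6):
            expr.append(run(f"a{i}", n=2, end=4))
            srna.append(run(f"a{i}", n=2, end=4))
        for i in range(2):
            expr.append(run(f"b{i}", n=2, end=4))
            srna.append(run(f"b{i}", n=1, start=4, end=4))
        for i in range(2):
            expr.append(run(f"c{i}", n=2, end=4))
            srna.append(run(f"c{i}", n=1, start=16, end=16))
        states = build_gene_states(expr, {"g22": srna})
        row = simultaneity_breakdown(states, "g22").iloc[0]
        assert row["simultaneous_inherited_pct"] == pytest.approx(60.0)
        assert row["simultaneous_non_inherited_pct"] == pytest.approx(20.0)
        assert row["non_simultaneous_pct"] == pytest.approx(20.0)


class TestClassComparison:
    def test_identical_classes_give_unit_odds(self):
        expr = [run(f"g{i}") for i in range(10)]
        srna = [run(f"g{i}") for i in range(5)]          # simultaneous
        srna += [run(f"g{i}", start=16, end=16) for i in range(5, 8)]  # not
        states = build_gene_states(expr, {"g22": srna, "trna_half": srna})
        res = class_comparison(states, "g22", "trna_half")
        assert res.odds_ratio == pytest.approx(1.0)

    def test_reproduces_printed_comparison_counts(self):
        # construction forcing the (75, 2; 912, 16) control table: genes
        # with both change types, split by simultaneity within each class
        expr, srna_a, srna_b = [], [], []
        gid = 0

        def add(n, cls_runs, simultaneous):
            nonlocal gid
            for _ in range(n):
                g = f"g{gid}"
                gid += 1
                expr.append(run(g, start=2, end=2))
                start = 2 if simultaneous else 16
                cls_runs.append(run(g, start=start, end=start))

        add(75, srna_a, True)
        add(912, srna_a, False)
        add(2, srna_b, True)
        add(16, srna_b, False)
        states = build_gene_states(expr, {"g22": srna_a, "trna_half": srna_b})
        res = class_comparison(states, "g22", "trna_half")
        assert (res.a, res.b, res.c, res.d) == (75, 2, 912, 16)
        assert f"{res.odds_ratio:.2f}" == "0.66"
        assert f"{res.p:.2f}" == "0.64"


class TestTermEnrichment:
    def test_minimum_gene_rule_excludes_sparse_terms(self):
        test = [f"t{i}" for i in range(10)]
        background = [f"b{i}" for i in range(100)]
        annotation = {g: {"rare"} for g in (test[:2] + background[:2])}
        annotation.update({g: {"common"} for g in test[:6]})
        table, n_excluded = term_enrichment(test, background, annotation)
        assert n_excluded == 1
        assert list(table["term"]) == ["common"]

    def test_balanced_annotation_gives_unit_odds(self):
        test = [f"t{i}" for i in range(20)]
        background = [f"b{i}" for i in range(20)]
        annotation = {g: {"T"} for g in test[:10] + background[:10]}
        table, _ = term_enrichment(test, background, annotation)
        assert table.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_hypergeometric_oracle_agreement(self):
        rng = np.random.default_rng(65)
        test = [f"t{i}" for i in range(30)]
        background = [f"b{i}" for i in range(200)]
        annotation = {}
        for g in test + background:
            terms = {f"T{j}" for j in range(5) if rng.random() < 0.3}
            if terms:
                annotation[g] = terms
        table, _ = term_enrichment(test, background, annotation)
        for _, row in table.iterrows():
            a, b, c, d = (int(row[k]) for k in "abcd")
            _, p_sp = stats.fisher_exact([[a, b], [c, d]])
            assert row["p"] == pytest.approx(p_sp, rel=1e-8, abs=1e-10)

    def test_bonferroni_applied(self):
        test = [f"t{i}" for i in range(20)]
        background = [f"b{i}" for i in range(50)]
        annotation = {g: {"T1", "T2"} for g in test[:8] + background[:5]}
        table, _ = term_enrichment(test, background, annotation)
        assert np.allclose(table["p_adj"], np.minimum(1.0, table["p"] * len(table)))

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            term_enrichment(["a"], ["a", "b"], {"a": {"T"}})


class TestTrnaTargetMapping:
    def test_type_level_runs_attach_to_target_genes(self):
        targets = pd.DataFrame(
            [{"gene": "geneA", "trna_type": "GlyGCC"},
             {"gene": "geneB", "trna_type": "GlyGCC"},
             {"gene": "geneC", "trna_type": "GluCTC"}]
        )
        trna_runs = [run("GlyGCC", start=4, end=6, n=2)]
        states = build_gene_states([run("geneA", start=4, end=4)],
                                   {"trna_half": trna_runs}, trna_targets=targets)
        assert states[("geneA", "C1")].has_simultaneous("trna_half")
        assert states[("geneB", "C1")].has_srna("trna_half")
        assert ("geneC", "C1") not in states
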