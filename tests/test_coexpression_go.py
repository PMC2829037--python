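"""Correlation null threshold, co-expression sets, Fisher/q-value machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import fisher_greater_oracle
from linspec.coexpression_go import (
    EXCLUDED_EVIDENCE_CODES,
    ExpressionMatrix,
    GoAnnotationTable,
    bh_adjust,
    coexpressed_genes,
    estimate_null_threshold,
    estimate_qvalues,
    fisher_term_enrichment,
    group_overrepresentation,
    pearson_cc,
)


def _normal_matrix(n_genes, m, seed):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(n_genes, m)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"e{j}" for j in range(m)],
        )
    )


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_cc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert math.isnan(pearson_cc([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_pairwise_complete_observations(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        ok = [0, 1, 3]
        expected = np.corrcoef(x[ok], y[ok])[0, 1]
        assert pearson_cc(x, y) == pytest.approx(expected)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(77)
        x, y = rng.normal(size=50), rng.normal(size=50)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_cc(x, y) == pytest.approx(num / den, abs=1e-12)


class TestNullThreshold:
    def test_matches_closed_form_for_iid_normal(self):
        """99th pct of sampled null PCCs vs the exact t-transform value."""
        m = 20
        matrix = _normal_matrix(2_000, m, seed=101)
        r_star = estimate_null_threshold(matrix, n_pairs=200_000, seed=5)
        t99 = stats.t.ppf(0.99, m - 2)
        exact = t99 / math.sqrt(m - 2 + t99**2)
        assert abs(r_star - exact) <= 0.02

    def test_identical_profiles_threshold_one(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=10)
        matrix = ExpressionMatrix(
            pd.DataFrame(
                np.tile(row, (50, 1)), index=[f"g{i}" for i in range(50)],
                columns=[f"e{j}" for j in range(10)],
            )
        )
        assert estimate_null_threshold(matrix, n_pairs=2_000, seed=1) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        matrix = _normal_matrix(200, 15, seed=8)
        a = estimate_null_threshold(matrix, n_pairs=5_000, seed=42)
        b = estimate_null_threshold(matrix, n_pairs=5_000, seed=42)
        assert a == b

    def test_calibration_on_held_out_pairs(self):
        """~1% of fresh random pairs exceed the estimated threshold."""
        matrix = _normal_matrix(1_000, 20, seed=13)
        r_star = estimate_null_threshold(matrix, n_pairs=100_000, seed=1)
        rng = np.random.default_rng(999)
        data = matrix.values.to_numpy()
        centered = data - data.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        i = rng.integers(0, 1_000, 50_000)
        j = rng.integers(0, 1_000, 50_000)
        keep = i != j
        i, j = i[keep], j[keep]
        rs = (centered[i] * centered[j]).sum(axis=1) / (norms[i] * norms[j])
        frac = float((rs > r_star).mean())
        assert abs(frac - 0.01) <= 0.002


class TestCoexpressedGenes:
    def test_duplicated_profile_always_included(self):
        matrix = _normal_matrix(20, 12, seed=21)
        matrix.values.loc["g1"] = matrix.values.loc["g0"]
        assert "g1" in coexpressed_genes("g0", matrix, r_star=0.99)

    def test_threshold_one_empty(self):
        matrix = _normal_matrix(20, 12, seed=22)
        assert coexpressed_genes("g0", matrix, r_star=1.0) == set()

    def test_absent_gene_raises(self):
        matrix = _normal_matrix(5, 8, seed=23)
        with pytest.raises(KeyError):
            coexpressed_genes("nope", matrix, 0.5)

    def test_planted_module_recovery(self, sim_spec, sim):
        from linspec.synthetic_data import simulate_expression_compendium

        matrix, _, modules = simulate_expression_compendium(
            sim_spec, sorted(sim.annotation.genes), seed=4
        )
        r_star = estimate_null_threshold(matrix, n_pairs=100_000, seed=4)
        members = modules["MOD1"]
        recovered = coexpressed_genes(members[0], matrix, r_star)
        assert len(recovered & set(members[1:])) >= 8


class TestFisher:
    def test_disjoint_partition_closed_form(self):
        go = GoAnnotationTable(
            pd.DataFrame(
                [
                    {"gene_id": f"g{i}", "go_id": "GO:1", "go_term": "t",
                     "evidence_code": "IDA"}
                    for i in range(10)
                ]
            )
        )
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(10)}
        rec = fisher_term_enrichment(gene_set, go, universe)[0]
        assert rec.p_value == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_whole_universe_term_p_one(self):
        go = GoAnnotationTable(
            pd.DataFrame(
                [
                    {"gene_id": f"g{i}", "go_id": "GO:1", "go_term": "t",
                     "evidence_code": "TAS"}
                    for i in range(10)
                ]
            )
        )
        universe = {f"g{i}" for i in range(10)}
        rec = fisher_term_enrichment({"g0", "g1"}, go, universe)[0]
        assert rec.p_value == pytest.approx(1.0)

    def test_excluded_evidence_codes_dropped(self):
        rows = [
            {"gene_id": "g1", "go_id": "GO:1", "go_term": "t", "evidence_code": c}
            for c in sorted(EXCLUDED_EVIDENCE_CODES)
        ] + [{"gene_id": "g1", "go_id": "GO:2", "go_term": "t", "evidence_code": "IDA"}]
        go = GoAnnotationTable(pd.DataFrame(rows))
        assert go.term_ids == ["GO:2"]

    def test_random_tables_match_tail_sum(self):
        rng = np.random.default_rng(404)
        for _ in range(500):
            a, b, c, d = (int(rng.integers(0, 30)) for _ in range(4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(
                fisher_greater_oracle(a, b, c, d), abs=1e-12
            )


class TestQvalues:
    def test_all_ones(self):
        assert np.all(estimate_qvalues([1.0, 1.0, 1.0]) == 1.0)

    def test_pi0_near_one_on_uniform(self):
        rng = np.random.default_rng(55)
        p = rng.uniform(size=10_000)
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
        pi0 = float(np.polyval(np.polyfit(lam, pi0_lam, 3), 1.0))
        assert 0.9 <= pi0 <= 1.1
        # q-values under the null stay close to BH
        q = estimate_qvalues(p)
        assert np.all(q <= 1.0)

    def test_q_equals_pi0_times_bh(self):
        rng = np.random.default_rng(56)
        p = rng.uniform(size=500) ** 2
        for pi0 in (0.5, 1.0):
            q = estimate_qvalues(p, pi0=pi0)
            assert np.allclose(q, np.minimum(1.0, pi0 * bh_adjust(p)), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(57)
        p = rng.uniform(size=300)
        q = estimate_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_type_one_control_on_null_enrichment(self):
        """Random GO labels on independent profiles: few q < 0.05 calls."""
        rng = np.random.default_rng(58)
        universe = {f"g{i}" for i in range(300)}
        flagged = total = 0
        for trial in range(50):
            gene_set = set(rng.choice(sorted(universe), size=30, replace=False))
            rows = []
            for t in range(20):
                members = rng.choice(sorted(universe), size=15, replace=False)
                rows += [
                    {"gene_id": g, "go_id": f"GO:{t}", "go_term": "t",
                     "evidence_code": "IDA"}
                    for g in members
                ]
            go = GoAnnotationTable(pd.DataFrame(rows))
            recs = fisher_term_enrichment(gene_set, go, universe)
            flagged += sum(1 for r in recs if r.q_value < 0.05)
            total += len(recs)
        assert flagged / total <= 0.05 + 0.02


class TestGroupOverrepresentation:
    def test_exclusive_group_significant(self):
        lineage = {f"l{i}" for i in range(100)}
        background = {f"b{i}" for i in range(900)}
        groups = {f"l{i}": "pollen" for i in range(20)}
        groups.update({f"b{i}": "defense" for i in range(50)})
        df = group_overrepresentation(lineage, background, groups, fdr=0.01)
        row = df[df.group == "pollen"].iloc[0]
        assert row.significant and row.p_value < 1e-6

    def test_identical_composition_not_significant(self):
        lineage = {f"l{i}" for i in range(50)}
        background = {f"b{i}" for i in range(50)}
        groups = {f"l{i}": "grp" for i in range(10)}
        groups.update({f"b{i}": "grp" for i in range(10)})
        df = group_overrepresentation(lineage, background, groups)
        assert not df.significant.any()

    def test_swapping_sets_reverses_direction(self):
        lineage = {f"l{i}" for i in range(100)}
        background = {f"b{i}" for i in range(100)}
        groups = {f"l{i}": "grp" for i in range(30)}
        groups.update({f"b{i}": "grp" for i in range(5)})
        forward = group_overrepresentation(lineage, background, groups)
        backward = group_overrepresentation(background, lineage, groups)
        assert forward.iloc[0].p_value < 0.01 < backward.iloc[0].p_value
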