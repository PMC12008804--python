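"""Exact small-sample tests, CN-adjusted expression, dosage model, DE,
and ORF utilities — cross-checked against independent oracles."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ampdel.io import ExpressionTable
from ampdel.simulate import (
    NEIGHBOR_LOCUS,
    TARGET_LOCUS,
    ExpressionModelCoeffs,
    SimConfig,
    emit_expression,
    simulate_cohort,
    simulate_de_matrix,
)
from ampdel.stats import (
    RankDeficientDesignError,
    cn_adjusted_expression,
    compare_locus_cn,
    cooccurrence_fisher,
    differential_expression,
    fit_dosage_model,
    orf_isoform_compare,
    orf_lfc,
    rank_sum_test,
)

from conftest import make_segments


def brute_force_ranksum_p(x, y):
    """Independent enumeration oracle: two-sided rank-sum p as the
    fraction of group assignments at least as extreme as observed."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_three_vs_three_exact(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 assignments are as extreme."""
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_zero_variance(self):
        res = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert "zero_variance" in res.flags

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            ours = rank_sum_test(x, y).p_value
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_path_agrees_with_enumeration_near_boundary(self):
        """Just above the exact-path cutoff (n = 13) the tie-corrected
        approximation must land close to full enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            x, y = rng.normal(size=6), rng.normal(size=7)
            approx = rank_sum_test(x, y).p_value  # combined n = 13 -> normal
            exact = brute_force_ranksum_p(x, y)
            assert approx == pytest.approx(exact, abs=0.05)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_exact_matches_brute_force_with_ties(self, data):
        vals = st.integers(0, 3)  # heavy ties on purpose
        n1 = data.draw(st.integers(1, 4))
        n2 = data.draw(st.integers(1, 4))
        x = np.array(data.draw(st.lists(vals, min_size=n1, max_size=n1)), float)
        y = np.array(data.draw(st.lists(vals, min_size=n2, max_size=n2)), float)
        if np.ptp(np.r_[x, y]) == 0:
            return
        assert rank_sum_test(x, y).p_value == pytest.approx(
            brute_force_ranksum_p(x, y), abs=1e-12
        )

    def test_carrier_power_grows_with_n(self):
        """Simulated carriers with higher CN: the rank-sum p decreases
        with sample size (monotone power)."""
        rng = np.random.default_rng(6)
        pvals = []
        for n in (20, 80, 320):
            carriers = rng.normal(6.5, 1.5, size=n // 4)
            rest = rng.normal(3.0, 1.5, size=n)
            pvals.append(compare_locus_cn(carriers, rest).p_value)
        assert pvals[0] > pvals[2]
        assert pvals[2] < 1e-6


class TestFisher:
    def test_three_one_one_three(self):
        res = cooccurrence_fisher(3, 1, 1, 3)
        assert res.p_value == pytest.approx(0.4857142857, abs=1e-9)

    def test_all_zero_row_is_one(self):
        assert cooccurrence_fisher(0, 0, 2, 3).p_value == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cooccurrence_fisher(-1, 2, 3, 4)

    @given(st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)))
    @settings(max_examples=300, deadline=None)
    def test_matches_scipy_fisher(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        ours = cooccurrence_fisher(a, b, c, d).p_value
        ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_cooccurrence_significant_when_planted(self):
        """Deletions heavily enriched in amplified samples at n=500."""
        sim = simulate_cohort(SimConfig(n_samples=500, seed=9))
        t = sim.truth.samples
        a = sum(x.has_amp and x.has_del for x in t)
        b = sum(x.has_amp and not x.has_del for x in t)
        c = sum((not x.has_amp) and x.has_del for x in t)
        d = sum((not x.has_amp) and not x.has_del for x in t)
        assert cooccurrence_fisher(a, b, c, d).p_value < 0.05


class TestCnAdjusted:
    def build(self, cn_neighbor):
        expr = ExpressionTable(pd.DataFrame({"s1": [10.0]}, index=["G"]))
        segs = {"s1": make_segments("s1", NEIGHBOR_LOCUS.chrom, [(0, 5_000_000, cn_neighbor)])}
        return cn_adjusted_expression(expr, segs, NEIGHBOR_LOCUS)

    def test_diploid_identity(self):
        assert self.build(2.0).values.loc["G", "s1"] == pytest.approx(10.0)

    def test_cn_four_halves(self):
        assert self.build(4.0).values.loc["G", "s1"] == pytest.approx(5.0)

    def test_nonpositive_cn_sample_dropped(self):
        out = self.build(0.0)
        assert out.values.shape[1] == 0

    def test_carrier_adjusted_expression_lower(self):
        """Negative deletion coefficient: carriers have lower adjusted
        target-gene expression (rank-sum p < 0.05 at n = 300)."""
        from ampdel.io import segments_by_sample

        sim = simulate_cohort(SimConfig(n_samples=300, seed=12))
        segs = segments_by_sample(sim.segments)
        adjusted = cn_adjusted_expression(sim.expression, segs, NEIGHBOR_LOCUS)
        carriers = {t.sample for t in sim.truth.carriers()}
        vals = adjusted.values.loc[TARGET_LOCUS.name]
        x = vals[[s for s in vals.index if s in carriers]]
        y = vals[[s for s in vals.index if s not in carriers]]
        res = rank_sum_test(x, y)
        assert np.median(x) < np.median(y)
        assert res.p_value < 0.05


class TestDosageModel:
    GEN = {"tumor_type[OV]": 26.1, "copy_number": 3.6, "focal_deletion": -6.3}

    @staticmethod
    def cohort_frames(sim):
        meta = sim.metadata.table.set_index("sample")
        cn = pd.Series({t.sample: t.target_locus_cn for t in sim.truth.samples})
        dl = pd.Series({t.sample: float(t.has_del) for t in sim.truth.samples})
        return meta, cn, dl

    def test_zero_noise_recovers_generative_coefficients_exactly(self):
        sim = simulate_cohort(SimConfig(n_samples=400, seed=5, expr_noise_sd=0.0))
        meta, cn, dl = self.cohort_frames(sim)
        fit = fit_dosage_model(
            sim.expression.values.loc[TARGET_LOCUS.name], cn, dl,
            meta["tumor_type"], meta["patient"],
        )
        for name, value in self.GEN.items():
            assert fit.coefficients[name] == pytest.approx(value, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(8.0, abs=1e-9)

    def test_duplicated_patient_collapsed_before_fit(self):
        """Fitting per-patient means differs from fitting duplicated rows."""
        rng = np.random.default_rng(8)
        n = 40
        expr = pd.Series(rng.normal(20, 4, n))
        cn = pd.Series(rng.integers(2, 6, n).astype(float))
        dl = pd.Series((rng.random(n) < 0.3).astype(float))
        tt = pd.Series(rng.choice(["OV", "Other"], n))
        # patient 0 profiled three times with different expression draws
        patient = pd.Series([f"p{max(i - 2, 0)}" for i in range(n)])
        collapsed = fit_dosage_model(expr, cn, dl, tt, patient)
        raw = fit_dosage_model(expr, cn, dl, tt, None)
        assert collapsed.n == n - 2
        assert collapsed.coefficients["copy_number"] != pytest.approx(
            raw.coefficients["copy_number"], abs=1e-12
        )

    def test_rank_deficient_design_names_columns(self):
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cn = pd.Series([2.0] * 6)  # constant -> collinear with intercept
        dl = pd.Series([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        tt = pd.Series(["OV", "OV", "Other", "Other", "OV", "Other"])
        with pytest.raises(RankDeficientDesignError, match="copy_number"):
            fit_dosage_model(expr, cn, dl, tt)

    def test_confidence_interval_coverage(self):
        """Over 60 noisy replicates, each generative coefficient falls in
        its own 95% CI at a rate consistent with nominal coverage."""
        cfg = SimConfig(n_samples=1000, seed=3)
        sim = simulate_cohort(cfg)
        meta, cn, dl = self.cohort_frames(sim)
        cover = dict.fromkeys(self.GEN, 0)
        reps = 60
        for r in range(reps):
            expr = emit_expression(sim.truth, cfg.expr_coeffs, 5.0, seed=2_000 + r)
            fit = fit_dosage_model(
                expr.values.loc[TARGET_LOCUS.name], cn, dl,
                meta["tumor_type"], meta["patient"],
            )
            for k in cover:
                lo, hi = fit.conf_int[k]
                cover[k] += lo <= self.GEN[k] <= hi
        for k, c in cover.items():
            # 3 SD band around 0.95 for 60 draws
            assert 0.95 * reps - 3 * np.sqrt(reps * 0.95 * 0.05) <= c <= reps


class TestDifferentialExpression:
    def test_planted_four_fold_signals_recovered_exactly(self):
        table, carrier, ttype, planted = simulate_de_matrix(
            n_genes=500, n_planted=10, fold_change=4.0, seed=17
        )
        de = differential_expression(table, carrier, ttype)
        assert set(de.loc[de.passed, "gene"]) == set(planted)
        top = de.head(10)
        assert top["log2fc"].mean() == pytest.approx(2.0, abs=0.2)

    def test_small_fold_change_fails_gate_despite_tiny_p(self):
        table, carrier, ttype, planted = simulate_de_matrix(
            n_genes=300, n_planted=10, fold_change=1.5, noise_sd_log2=0.05, seed=18
        )
        de = differential_expression(table, carrier, ttype)
        planted_rows = de[de["gene"].isin(planted)]
        assert (planted_rows["q"] < 0.1).all()
        assert not planted_rows["passed"].any()

    def test_zero_variance_gene_flagged_never_passes(self):
        table, carrier, ttype, _ = simulate_de_matrix(n_genes=20, n_planted=0, seed=19)
        vals = table.values.copy()
        vals.iloc[0, :] = 7.0
        de = differential_expression(ExpressionTable(vals), carrier, ttype)
        row = de[de["gene"] == vals.index[0]].iloc[0]
        assert row["zero_variance"] and row["p"] == 1.0 and not row["passed"]

    def test_bonferroni_dominates_and_pass_set_shrinks(self):
        table, carrier, ttype, planted = simulate_de_matrix(
            n_genes=400, n_planted=5, fold_change=2.5, noise_sd_log2=0.6, seed=20
        )
        de_all = differential_expression(table, carrier, ttype)
        assert (de_all["q"] >= de_all["p"] - 1e-15).all()
        de_small = differential_expression(table, carrier, ttype, genes=list(table.features[:100]))
        passed_small = set(de_small.loc[de_small.passed, "gene"])
        passed_all = set(de_all.loc[de_all.passed, "gene"]) & set(table.features[:100])
        # a larger universe means a harsher Bonferroni factor
        assert passed_all <= passed_small

    def test_too_few_carriers_rejected(self):
        table, carrier, ttype, _ = simulate_de_matrix(n_genes=10, n_carriers=1, seed=21)
        with pytest.raises(ValueError, match="carriers"):
            differential_expression(table, carrier, ttype)


class TestOrf:
    def test_identity_and_toxicity_sign(self):
        assert orf_lfc(100.0, 100.0) == pytest.approx(0.0)
        assert orf_lfc(100.0, 25.0) == pytest.approx(-2.0)

    def test_zero_abundance_with_zero_pseudocount_undefined(self):
        with pytest.raises(ValueError, match="pseudocount"):
            orf_lfc(0.0, 0.0)

    def test_paired_t_limit_with_constant_offset(self):
        rng = np.random.default_rng(23)
        long = rng.normal(0.0, 1.0, size=12)
        for sd in (0.3, 0.03):
            short = long - 1.0 + rng.normal(0.0, sd, size=12)
            res = orf_isoform_compare(long, short)
            assert res.p_value < 0.05
        assert orf_isoform_compare(long, long - 1.0).p_value < 1e-12
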