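"""Within-cohort fits: main effects, interactions, variance explained,
medication tabulation/enrichment and stratified means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvdose.cohort_assoc import (
    fit_interaction, fit_main_effect, medication_enrichment, stratified_means,
    tabulate_medications, variance_explained,
)
from cnvdose.locus_model import DEL, DUP, NO_CALL, REF


def make_cohort(rng, n, carriers_del=0, carriers_dup=0, beta_del=0.0,
                beta_dup=0.0, gamma_pgs=0.0, sex_delta=0.0, pgs_beta=0.0,
                n_pcs=10, pc1_effect=0.0, pc1_carrier_shift=0.0):
    geno = np.array([REF] * n, dtype=object)
    idx = rng.permutation(n)
    geno[idx[:carriers_del]] = DEL
    geno[idx[carriers_del:carriers_del + carriers_dup]] = DUP
    pcs = rng.standard_normal((n, n_pcs))
    pgs = rng.standard_normal(n)
    sex_f = (rng.random(n) < 0.5).astype(float)
    d = (geno == DEL).astype(float)
    u = (geno == DUP).astype(float)
    if pc1_carrier_shift:
        pcs[:, 0] += pc1_carrier_shift * d
    y = (
        beta_del * d + beta_dup * u
        + gamma_pgs * d * pgs + sex_delta * d * sex_f
        + pgs_beta * pgs + pc1_effect * pcs[:, 0]
        + rng.standard_normal(n)
    )
    df = pd.DataFrame({"y": y, "span": geno, "PGS": pgs,
                       "sex": np.where(sex_f > 0, "F", "M")})
    for j in range(n_pcs):
        df[f"PC{j+1}"] = pcs[:, j]
    return df


class TestMainEffect:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        df = make_cohort(rng, 400, carriers_del=30, carriers_dup=20,
                         beta_del=-0.5, beta_dup=0.3)
        res = {r.allele: r for r in fit_main_effect(df, "y", "span")}
        X = np.column_stack(
            [np.ones(len(df)), (df["span"] == DEL), (df["span"] == DUP)]
            + [df[f"PC{j+1}"] for j in range(10)]
        ).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res[DEL].beta == pytest.approx(beta[1], abs=1e-10)
        assert res[DUP].beta == pytest.approx(beta[2], abs=1e-10)

    def test_label_flip_equivariance(self):
        rng = np.random.default_rng(1)
        df = make_cohort(rng, 1000, carriers_del=40, carriers_dup=25,
                         beta_del=-0.4, beta_dup=0.2)
        res = {r.allele: r for r in fit_main_effect(df, "y", "span")}
        flipped = df.assign(
            span=df["span"].map({DEL: DUP, DUP: DEL, REF: REF})
        )
        fres = {r.allele: r for r in fit_main_effect(flipped, "y", "span")}
        assert res[DEL].beta == pytest.approx(fres[DUP].beta, abs=1e-12)
        assert res[DUP].beta == pytest.approx(fres[DEL].beta, abs=1e-12)

    def test_recovery_within_ci(self):
        rng = np.random.default_rng(2)
        df = make_cohort(rng, 50_000, carriers_del=500, beta_del=-0.5)
        r = fit_main_effect(df, "y", "span")[0]
        assert r.allele == DEL
        assert abs(r.beta - (-0.5)) < 3 * r.se
        assert r.n_carriers == 500

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(300):
            df = make_cohort(rng, 1_500, carriers_del=40, n_pcs=2)
            pvals.append(fit_main_effect(df, "y", "span")[0].p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_pc_adjustment_removes_planted_confounding(self):
        rng = np.random.default_rng(4)
        df = make_cohort(rng, 40_000, carriers_del=400, beta_del=-0.3,
                         pc1_effect=0.5, pc1_carrier_shift=1.5)
        adj = fit_main_effect(df, "y", "span")[0]
        unadj = fit_main_effect(df, "y", "span", pc_cols=[])[0]
        assert abs(adj.beta - (-0.3)) < 3 * adj.se
        # unadjusted absorbs the PC-mediated shift 0.5 * 1.5
        assert abs(unadj.beta - (-0.3)) > 5 * adj.se

    def test_no_call_dropped_per_span(self):
        rng = np.random.default_rng(5)
        df = make_cohort(rng, 500, carriers_del=20)
        df.loc[df.index[:50], "span"] = NO_CALL
        r = fit_main_effect(df, "y", "span")[0]
        assert r.n_total == 450

    def test_no_carriers_raises(self):
        rng = np.random.default_rng(6)
        df = make_cohort(rng, 100)
        with pytest.raises(ValueError, match="no DEL or DUP"):
            fit_main_effect(df, "y", "span")


class TestInteraction:
    def test_planted_pgs_interaction_recovered(self):
        rng = np.random.default_rng(7)
        est = []
        for _ in range(60):
            df = make_cohort(rng, 8_000, carriers_del=500, beta_del=-0.3,
                             gamma_pgs=0.2, pgs_beta=0.4, n_pcs=2)
            r = [x for x in fit_interaction(df, "y", "span", "PGS")
                 if x.allele == DEL][0]
            est.append(r.beta)
        assert np.mean(est) == pytest.approx(0.2, abs=0.02)

    def test_additive_null_z_standard_normal(self):
        rng = np.random.default_rng(8)
        zs = []
        for _ in range(400):
            df = make_cohort(rng, 3_000, carriers_del=150, beta_del=-0.3,
                             pgs_beta=0.4, n_pcs=2)
            r = fit_interaction(df, "y", "span", "PGS")[0]
            zs.append(r.beta / r.se)
        zs = np.array(zs)
        assert abs(zs.mean()) < 3.0 / np.sqrt(len(zs))
        assert zs.std() == pytest.approx(1.0, abs=0.12)

    def test_sex_moderator_contrast_sign(self):
        """A planted female-specific excess gives a positive F-minus-M
        interaction contrast in >= 95% of simulations."""
        rng = np.random.default_rng(9)
        correct = 0
        n_rep = 40
        for _ in range(n_rep):
            df = make_cohort(rng, 10_000, carriers_del=400, beta_del=-0.2,
                             sex_delta=0.4, n_pcs=2)
            # pin the factor coding: make the first row male so M=0, F=1
            first_m = df.index[df["sex"] == "M"][0]
            df = pd.concat([df.loc[[first_m]], df.drop(index=first_m)])
            r = fit_interaction(df, "y", "span", "sex")[0]
            correct += r.beta > 0
        assert correct >= int(0.95 * n_rep)

    def test_constant_moderator_rejected(self):
        rng = np.random.default_rng(10)
        df = make_cohort(rng, 500, carriers_del=20)
        df["sex"] = "F"
        with pytest.raises(ValueError, match="constant|2 levels"):
            fit_interaction(df, "y", "span", "sex")

    def test_carrier_filter_enforced_when_requested(self):
        rng = np.random.default_rng(11)
        df = make_cohort(rng, 2_000, carriers_del=50)
        with pytest.raises(ValueError, match="carriers"):
            fit_interaction(df, "y", "span", "PGS", min_carriers=200)


class TestVarianceExplained:
    def test_null_delta_bounded(self):
        rng = np.random.default_rng(12)
        n = 20_000
        df = make_cohort(rng, n, carriers_del=40, carriers_dup=30)
        full, cov, delta, n_used = variance_explained(df, "y", ["span"])
        assert full >= cov
        assert 0 <= delta < 2 * 2 / n * 10  # k=2 indicators, generous bound

    def test_rare_indicator_analytic_value(self):
        rng = np.random.default_rng(13)
        n = 100_000
        f, beta = 0.004, 0.6
        df = make_cohort(rng, n, carriers_del=int(f * n), beta_del=beta,
                         n_pcs=2)
        _, _, delta, _ = variance_explained(df, "y", ["span"], pc_cols=[])
        expect = f * (1 - f) * beta**2  # variance of a rare indicator effect
        assert delta == pytest.approx(expect, rel=0.2)

    def test_nesting_always(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            df = make_cohort(rng, 2_000, carriers_del=25, carriers_dup=25)
            full, cov, delta, _ = variance_explained(df, "y", ["span"])
            assert delta >= -1e-12


class TestMedications:
    DICT = pd.DataFrame({
        "code": ["A1", "A2", "P1", "M1"],
        "category": ["antidepressant", "antidepressant", "antipsychotic",
                     "mood_stabilizer"],
    })

    def test_single_category(self):
        flags = tabulate_medications({"s1": ["A1"]}, self.DICT)
        row = flags.set_index("sample_id").loc["s1"]
        assert row["antidepressant"] and row["any"]
        assert not row["antipsychotic"] and not row["mood_stabilizer"]

    def test_empty_list_all_false(self):
        flags = tabulate_medications({"s1": []}, self.DICT)
        assert not flags.drop(columns="sample_id").any().any()

    def test_all_categories_union(self):
        flags = tabulate_medications({"s1": ["A2", "P1", "M1"]}, self.DICT)
        assert flags.drop(columns="sample_id").all().all()

    def test_unknown_codes_logged_not_fatal(self, caplog):
        flags = tabulate_medications({"s1": ["ZZZ", "A1"]}, self.DICT)
        assert flags.iloc[0]["antidepressant"]

    def test_chi_square_hand_example(self):
        """[[30,70],[10,90]] gives chi2 = 12.5 on 1 df (no correction)."""
        df = pd.DataFrame({
            "span": [DEL] * 100 + [REF] * 100,
            "med": [True] * 30 + [False] * 70 + [True] * 10 + [False] * 90,
        })
        chi2, p, table = medication_enrichment(df, "span", "med")
        assert chi2 == pytest.approx(12.5, abs=1e-10)
        np.testing.assert_array_equal(table, [[30, 70], [10, 90]])

    def test_equal_proportions_zero(self):
        df = pd.DataFrame({
            "span": [DUP] * 100 + [REF] * 200,
            "med": ([True] * 30 + [False] * 70) + ([True] * 60 + [False] * 140),
        })
        chi2, _, _ = medication_enrichment(df, "span", "med")
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_enrichment_power_at_planted_or(self):
        """Planted OR = 2 with 500 carriers is detected with power > 0.9."""
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            n, ncar = 20_000, 500
            carrier = np.zeros(n, bool)
            carrier[:ncar] = True
            base = 0.10
            odds = base / (1 - base) * np.where(carrier, 2.0, 1.0)
            p = odds / (1 + odds)
            use = rng.random(n) < p
            df = pd.DataFrame({
                "span": np.where(carrier, DEL, REF), "med": use
            })
            _, pval, _ = medication_enrichment(df, "span", "med")
            hits += pval < 0.05
        assert hits / n_rep > 0.9


class TestStratifiedMeans:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(16)
        df = make_cohort(rng, 5_000, carriers_del=100, carriers_dup=80,
                         beta_del=-0.5, beta_dup=0.5, pgs_beta=0.4)
        t1, r1 = stratified_means(df, "y", "span", pgs_col="PGS")
        shuffled = df.sample(frac=1.0, random_state=1)
        t2, r2 = stratified_means(shuffled, "y", "span", pgs_col="PGS")
        pd.testing.assert_frame_equal(t1, t2)
        assert r1 == r2

    def test_additive_range_matches_closed_form(self):
        """Planted -0.5/+0.5 CNV + 0.4/SD PGS: range across genotype x
        quartile cells matches the analytic additive expectation within 10%."""
        rng = np.random.default_rng(17)
        n = 100_000
        df = make_cohort(rng, n, carriers_del=int(0.005 * n),
                         carriers_dup=int(0.005 * n), beta_del=-0.5,
                         beta_dup=0.5, pgs_beta=0.4, n_pcs=1)
        _, rng_obs = stratified_means(df, "y", "span", pgs_col="PGS")
        # E[Z | quartile] for a standard normal: +-1.27, +-0.32
        q = np.array([stats.norm.ppf([i / 4, (i + 1) / 4]) for i in range(4)])
        qmeans = [
            (stats.norm.pdf(a) - stats.norm.pdf(b)) / 0.25
            for a, b in q
        ]
        expect = (0.5 + 0.5) + 0.4 * (max(qmeans) - min(qmeans))
        assert rng_obs == pytest.approx(expect, rel=0.10)

    def test_empty_cells_reported_excluded_from_range(self):
        rng = np.random.default_rng(18)
        df = make_cohort(rng, 400, carriers_del=3, pgs_beta=0.4)
        table, rng_obs = stratified_means(df, "y", "span", pgs_col="PGS")
        assert (table["n"] == 0).any()
        assert np.isfinite(rng_obs)
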