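import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from eitvent.io_formats import PHASES
from eitvent.stats import (fit_phase_lmm, icc_agreement, posthoc_contrasts,
                           residual_diagnostics, session_icc,
                           simulate_phase_response)

FLAT = {ph: 5.0 for ph in PHASES}


def classical_rm_anova(table: pd.DataFrame, variable: str):
    """Closed-form one-way repeated-measures ANOVA (balanced, one obs per
    subject x phase): the exact-reference F for the mixed model."""
    wide = table.pivot(index="animal", columns="phase", values=variable).to_numpy()
    n, p = wide.shape
    grand = wide.mean()
    ss_subj = p * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_phase = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((wide - grand) ** 2).sum() - ss_subj - ss_phase
    df1, df2 = p - 1, (p - 1) * (n - 1)
    return (ss_phase / df1) / (ss_err / df2), df1, df2


class TestMixedModel:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_balanced_design_matches_classical_anova(self, seed):
        rng = np.random.default_rng(seed)
        table = simulate_phase_response(FLAT, 1.0, 1.0, 6, 1, rng)
        model = fit_phase_lmm(table, "y")
        f_ref, df1, df2 = classical_rm_anova(table, "y")
        assert model.f_stat == pytest.approx(f_ref, rel=1e-6)
        assert model.df_num == df1
        assert model.df_den == pytest.approx(df2, rel=1e-6)

    def test_two_sessions_give_classical_72_denominator_df(self):
        rng = np.random.default_rng(4)
        table = simulate_phase_response(FLAT, 1.0, 1.0, 6, 2, rng)
        model = fit_phase_lmm(table, "y")
        assert model.df_den == pytest.approx(72.0, rel=1e-6)

    def test_constant_response_is_degenerate(self):
        rng = np.random.default_rng(0)
        table = simulate_phase_response(FLAT, 0.0, 0.0, 6, 2, rng)
        with pytest.raises(ValueError, match="degenerate"):
            fit_phase_lmm(table, "y")

    def test_zero_subject_variance_flagged_singular_not_fatal(self):
        # true subject variance is zero; this draw puts the REML estimate
        # on the boundary
        rng = np.random.default_rng(2)
        table = simulate_phase_response(FLAT, 0.0, 1.0, 6, 2, rng)
        model = fit_phase_lmm(table, "y")
        assert model.singular
        assert np.isfinite(model.p_value)

    def test_missing_phases_reduce_n_without_imputation(self):
        rng = np.random.default_rng(6)
        table = simulate_phase_response(FLAT, 1.0, 1.0, 6, 2, rng)
        table = table.drop(index=range(5)).reset_index(drop=True)
        model = fit_phase_lmm(table, "y")
        assert model.fit.n_obs == 79
        assert np.isfinite(model.f_stat)

    def test_matches_lmerTest_satterthwaite_on_unbalanced_data(self, tmp_path):
        """Independent oracle: lmerTest/emmeans (REML + Satterthwaite) on an
        unbalanced two-session table with a real phase effect."""
        rng = np.random.default_rng(42)
        means = dict(zip(PHASES, [10, 6, 5, 5, 5.5, 5, 7]))
        table = simulate_phase_response(means, 2.0, 1.0, 6, 2, rng)
        table = table.drop(index=[3, 4, 5, 6, 70, 83]).reset_index(drop=True)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages({{library(lmerTest); library(emmeans); library(jsonlite)}})
d <- read.csv('{csv}')
d$phase <- factor(d$phase)
m <- lmer(y ~ phase + (1|animal), data=d, REML=TRUE)
a <- anova(m)
vc <- as.data.frame(VarCorr(m))
em <- emmeans(m, ~phase, lmer.df='satterthwaite')
pr <- as.data.frame(pairs(em, adjust='tukey'))
cat(toJSON(list(F=a$'F value', ddf=a$DenDF, p=a$'Pr(>F)',
  s2a=vc$vcov[1], s2e=vc$vcov[2],
  contrast=pr$contrast, est=pr$estimate, se=pr$SE, cdf=pr$df,
  padj=pr$p.value), digits=10))
""")
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript oracle not available"
        out = subprocess.run([rscript, str(script)], capture_output=True,
                             text=True, check=True).stdout
        ref = json.loads(out[out.index("{"):])
        model = fit_phase_lmm(table, "y")
        assert model.f_stat == pytest.approx(ref["F"][0], rel=1e-6)
        assert model.df_den == pytest.approx(ref["ddf"][0], rel=1e-4)
        assert model.p_value == pytest.approx(ref["p"][0], rel=1e-4)
        assert model.sigma2_subject == pytest.approx(ref["s2a"][0], rel=1e-5)
        assert model.sigma2_resid == pytest.approx(ref["s2e"][0], rel=1e-5)
        ours = {frozenset((c.phase_a, c.phase_b)):
                c for c in posthoc_contrasts(model)}
        assert len(ours) == 21
        for name, est, se, cdf, padj in zip(ref["contrast"], ref["est"],
                                            ref["se"], ref["cdf"], ref["padj"]):
            a, b = [s.strip("() ") for s in name.split(" - ")]
            c = ours[frozenset((a, b))]
            assert abs(c.estimate) == pytest.approx(abs(est), rel=1e-6)
            assert c.se == pytest.approx(se, rel=1e-5)
            assert c.df == pytest.approx(cdf, rel=1e-4)
            assert c.p_adjusted == pytest.approx(padj, rel=1e-3, abs=1e-6)


class TestContrasts:
    def test_identical_phase_means_give_zero_estimate(self):
        rng = np.random.default_rng(0)
        table = simulate_phase_response(FLAT, 1.0, 0.0, 6, 2, rng)
        # noise-free given the subject effect: all phase EMMs identical
        model = fit_phase_lmm(table, "y")
        for c in posthoc_contrasts(model):
            assert c.estimate == pytest.approx(0.0, abs=1e-9)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(11)
        means = dict(zip(PHASES, [8, 5, 5, 5, 5, 5, 6]))
        table = simulate_phase_response(means, 1.0, 1.0, 6, 2, rng)
        model = fit_phase_lmm(table, "y")
        for c in posthoc_contrasts(model):
            assert c.p_adjusted >= c.p_unadjusted - 1e-12
            assert c.t_stat == pytest.approx(c.estimate / c.se)

    def test_shifted_phase_dominates_smallest_adjusted_p(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            means = dict(zip(PHASES, [5.0] * 7))
            means["Sternal_CMVlow"] = 5.0 + 3.0  # 3 residual SDs
            table = simulate_phase_response(means, 1.0, 1.0, 6, 2, rng)
            model = fit_phase_lmm(table, "y")
            cs = sorted(posthoc_contrasts(model), key=lambda c: c.p_adjusted)
            top = cs[:6]
            if all("Sternal_CMVlow" in (c.phase_a, c.phase_b) for c in top):
                hits += 1
        assert hits >= 0.95 * n_rep - 2  # binomial slack at n=40


class TestDiagnostics:
    def test_normal_residuals_pass_screen(self):
        rng = np.random.default_rng(21)
        table = simulate_phase_response(FLAT, 1.0, 1.0, 6, 2, rng)
        d = residual_diagnostics(fit_phase_lmm(table, "y"))
        assert d.normality_ok
        # QQ data hugs the diagonal
        slope = np.polyfit(d.qq_theoretical, d.qq_sample, 1)[0]
        assert slope == pytest.approx(np.std(d.residuals), rel=0.2)

    def test_heavy_tailed_residuals_flagged(self):
        rng = np.random.default_rng(22)
        table = simulate_phase_response(FLAT, 1.0, 0.0, 6, 2, rng)
        table["y"] += rng.standard_t(2, size=len(table))
        d = residual_diagnostics(fit_phase_lmm(table, "y"))
        assert not d.normality_ok

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(23)
        table = simulate_phase_response(FLAT, 1.0, 1.0, 6, 2, rng)
        model = fit_phase_lmm(table, "y")
        model.fit.n_obs = 2
        with pytest.raises(ValueError, match="at least 3"):
            residual_diagnostics(model)


class TestICC:
    def test_identical_sessions_give_exactly_one(self):
        rows = []
        rng = np.random.default_rng(31)
        vals = rng.random(21) * 10
        for i, v in enumerate(vals):
            for s in (1, 2):
                rows.append({"animal": f"A{i % 6 + 1}", "session": s,
                             "phase": PHASES[i % 7], "x": v})
        res = session_icc(pd.DataFrame(rows), "x")
        assert res.icc == 1.0

    def test_constant_offset_penalised_below_one(self):
        Y = np.column_stack([np.arange(10.0), np.arange(10.0) + 2.0])
        icc, lo, hi = icc_agreement(Y)
        assert icc < 1.0
        # absolute-agreement closed form: row variance vs offset term
        k, n = 2, 10
        msr = 2 * np.var(np.arange(10.0) + 1.0, ddof=1)
        msc = n * 2.0 ** 2 / 2  # offset c: MSC = n c^2 / 2 with k - 1 = 1
        mse = 0.0
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pingouin_closed_form_on_random_matrices(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        Y = rng.normal(5, 2, (n, 2)) + rng.normal(0, 3, (n, 1))
        icc, lo, hi = icc_agreement(Y)
        df = pd.DataFrame({"targets": np.repeat(np.arange(n), 2),
                           "raters": np.tile([1, 2], n),
                           "score": Y.ravel()})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin reports the CI rounded to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=6e-3)

    def test_independent_sessions_centre_on_zero(self):
        rng = np.random.default_rng(33)
        Y = rng.normal(0, 1, (500, 2))
        icc, _, _ = icc_agreement(Y)
        assert abs(icc) < 0.12  # Monte-Carlo error at n=500

    def test_incomplete_pairs_dropped_and_counted(self):
        rng = np.random.default_rng(34)
        rows = []
        for a in range(1, 7):
            for ph in PHASES:
                for s in (1, 2):
                    rows.append({"animal": f"A{a}", "session": s,
                                 "phase": ph, "x": rng.random()})
        table = pd.DataFrame(rows)
        mask = ~((table["animal"] == "A4") & (table["session"] == 2)
                 & (table["phase"].isin(PHASES[3:])))
        res = session_icc(table[mask], "x")
        assert res.n_pairs == 38 and res.n_dropped == 4

    def test_too_few_pairs_rejected(self):
        table = pd.DataFrame([
            {"animal": "A1", "session": s, "phase": "Stand_pre", "x": 1.0 + s}
            for s in (1, 2)])
        with pytest.raises(ValueError, match="complete session pairs"):
            session_icc(table, "x")
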