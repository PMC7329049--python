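"""Classifier and GLMM behaviour: separability limits, chance levels,
agreement bounds, the plain-logit degenerate case, an external mixed-model
cross-check, and AICc selection rules."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vocaffect import predmodels as pm

SIX = ("scog", "duration", "f0_mean", "f0_sd", "hnr_mean", "hnr_max")


def glmm_trials(n_part=50, n_call=66, n_trial=155, beta0=0.3, beta=(0.5,),
                sd_p=0.5, sd_c=0.3, seed=0):
    """Trials with known per-SD log-odds effects and crossed intercepts."""
    rng = np.random.default_rng(seed)
    rows = n_part * n_trial
    pidx = np.repeat(np.arange(n_part), n_trial)
    cidx = rng.integers(0, n_call, rows)
    X = rng.standard_normal((rows, len(beta)))
    u = rng.normal(0, sd_p, n_part)
    v = rng.normal(0, sd_c, n_call)
    eta = beta0 + X @ np.asarray(beta) + u[pidx] + v[cidx]
    y = (rng.random(rows) < expit(eta)).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(len(beta))])
    df["participant_id"] = pidx
    df["caller_id"] = cidx
    df["correct"] = y
    return df


class TestClassifier:
    def test_disjoint_supports_are_perfectly_separated(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": np.r_[rng.uniform(0, 1, 30),
                                     rng.uniform(3, 4, 30)],
                          "b": rng.standard_normal(60)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pm.fit_classifier(X, ["lo"] * 30 + ["hi"] * 30, "valence")
        assert fit.agreement == 100.0
        assert fit.ridge_stabilized  # separation detected and stabilized

    def test_permuted_labels_are_at_chance_out_of_sample(self, corpus,
                                                         corpus_features):
        """Cross-validated agreement under label permutation sits at 1/k.

        In-sample agreement is upward-biased by the 63 free parameters, so
        chance level is only recovered out of sample.
        """
        stimuli, _ = corpus
        tab = stimuli.merge(corpus_features, on="stimulus_id").dropna(
            subset=list(SIX))
        rng = np.random.default_rng(1)
        cv_aggs, in_aggs = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(15):
                y = rng.permutation(tab["context_id"].to_numpy())
                fit = pm.fit_classifier(tab[list(SIX)], y, "context", cv=5)
                cv_aggs.append(fit.agreement_cv)
                in_aggs.append(fit.agreement)
        assert np.mean(cv_aggs) == pytest.approx(10.0, abs=4.0)
        assert np.mean(in_aggs) > np.mean(cv_aggs)  # overfitting direction

    def test_true_labels_beat_majority_baseline(self, corpus, corpus_features):
        stimuli, _ = corpus
        tab = stimuli.merge(corpus_features, on="stimulus_id").dropna(
            subset=list(SIX))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pm.fit_classifier(tab[list(SIX)], tab["context_id"], "context")
        baseline = 100 * tab["context_id"].value_counts(normalize=True).max()
        assert fit.agreement > baseline
        assert fit.overall_chi2 >= 0
        assert (fit.predictor_tests["lr_chi2"] >= 0).all()

    def test_fit_never_below_intercept_only(self):
        """The ML fit dominates the intercept-only model in likelihood on
        every dataset, and in agreement on average (0-1 accuracy is not
        monotone in likelihood, so single datasets may dip below the
        majority share)."""
        rng = np.random.default_rng(2)
        margins = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                n, k = 60, int(rng.integers(2, 4))
                X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
                y = rng.integers(0, k, n)
                if pd.Series(y).value_counts().min() < 2:
                    continue
                fit = pm.fit_classifier(X, y, "context")
                assert fit.overall_chi2 >= -1e-9  # 2*(ll_full - ll_null)
                baseline = 100 * pd.Series(y).value_counts(normalize=True).max()
                margins.append(fit.agreement - baseline)
        assert np.mean(margins) >= 0.0

    def test_requires_two_per_class(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            pm.fit_classifier(X, ["x", "x", "y"], "valence")


class TestGLMM:
    def test_zero_variance_matches_plain_logit(self):
        """With both random-effect variances at 0 the GLMM is a logit."""
        import statsmodels.api as sm

        df = glmm_trials(n_part=20, n_trial=40, seed=3)
        fit = pm.fit_accuracy_glmm(df, ["x1"], include_random=False)
        Xs = (df["x1"] - df["x1"].mean()) / df["x1"].std(ddof=1)
        X = np.column_stack([np.ones(len(df)), Xs])
        ref = sm.Logit(df["correct"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.fixed["estimate"], ref.params, atol=1e-4)
        assert fit.var_participant == 0.0 and fit.var_chimp == 0.0

    def test_null_effect_z_calibration(self):
        """A feature with zero true effect stays under |z|<1.96 in >=90%."""
        hits = 0
        reps = 50
        for s in range(reps):
            df = glmm_trials(n_part=50, n_trial=155, beta=(0.0,),
                             sd_p=0.5, sd_c=0.3, seed=100 + s)
            fit = pm.fit_accuracy_glmm(df, ["x1"])
            hits += abs(fit.fixed.loc[1, "z"]) < 1.96
        assert hits / reps >= 0.90

    def test_effect_and_variance_recovery(self):
        """Light recovery check; the deeper 20-replicate one runs elsewhere."""
        betas, vps = [], []
        for s in range(6):
            df = glmm_trials(n_part=80, n_trial=155, beta=(0.5,), sd_p=1.0,
                             sd_c=0.3, seed=200 + s)
            fit = pm.fit_accuracy_glmm(df, ["x1"])
            betas.append(fit.fixed.loc[1, "estimate"])
            vps.append(fit.var_participant)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.1)
        assert np.mean(vps) == pytest.approx(1.0, rel=0.30)

    def test_against_reference_mixed_model_implementation(self, tmp_path):
        """Fixed effects, variances and AIC match lme4's Laplace glmer."""
        df = glmm_trials(n_part=40, n_call=12, n_trial=50, beta=(0.6, -0.3),
                         sd_p=0.8, sd_c=0.5, seed=7)
        fit = pm.fit_accuracy_glmm(df, ["x1", "x2"])
        csv = tmp_path / "trials.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$x1 <- scale(d$x1); d$x2 <- scale(d$x2)
m <- glmer(correct ~ x1 + x2 + (1|participant_id) + (1|caller_id),
           data=d, family=binomial, control=glmerControl(optimizer="bobyqa"))
co <- fixef(m); vc <- as.data.frame(VarCorr(m))
cat(co, vc$vcov, AIC(m), sep="\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(x) for x in out.stdout.strip().splitlines()]
        ref_beta, ref_vars, ref_aic = vals[:3], vals[3:5], vals[5]
        np.testing.assert_allclose(fit.fixed["estimate"], ref_beta, atol=0.01)
        # VarCorr rows are sorted by grouping factor name (caller before participant)
        np.testing.assert_allclose(
            sorted([fit.var_participant, fit.var_chimp]), sorted(ref_vars),
            rtol=0.05, atol=5e-3)
        assert fit.aic == pytest.approx(ref_aic, abs=0.5)

    def test_requires_crossed_factors(self):
        df = glmm_trials(n_part=1, n_trial=30)
        with pytest.raises(ValueError):
            pm.fit_accuracy_glmm(df, ["x1"])


class TestAICSelection:
    @staticmethod
    def _fits(df, features):
        cands = pm.candidate_feature_sets(features)
        return {name: pm.fit_accuracy_glmm(df, fs, include_random=False)
                for name, fs in cands.items()}

    def test_min_delta_is_zero_and_ties_keep_full(self):
        fit_a = pm.fit_accuracy_glmm(glmm_trials(n_part=10, n_trial=30, seed=1),
                                     ["x1"], include_random=False)
        fits = {"full": fit_a, "drop_x1": fit_a}  # artificial exact tie
        sel = pm.aic_select(fits)
        assert sel.chosen == "full"
        assert sel.table["delta_aic"].min() == 0.0

    def test_differing_trial_sets_rejected(self):
        a = pm.fit_accuracy_glmm(glmm_trials(n_part=10, n_trial=30, seed=1),
                                 ["x1"], include_random=False)
        b = pm.fit_accuracy_glmm(glmm_trials(n_part=12, n_trial=30, seed=2),
                                 ["x1"], include_random=False)
        with pytest.raises(ValueError, match="differing"):
            pm.aic_select({"full": a, "drop_x1": b})

    def test_pure_noise_feature_is_dropped(self):
        """The leave-out model excluding a null feature wins most replicates."""
        wins = 0
        reps = 200
        for s in range(reps):
            df = glmm_trials(n_part=6, n_trial=100, beta=(0.8, -0.8, 0.0),
                             sd_p=0.0, sd_c=0.0, seed=300 + s)
            sel = pm.aic_select(self._fits(df, ("x1", "x2", "x3")))
            wins += sel.chosen == "drop_x3"
        assert wins / reps >= 0.80

    def test_informative_feature_is_kept(self):
        df = glmm_trials(n_part=20, n_trial=100, beta=(0.8, -0.8), sd_p=0.0,
                         sd_c=0.0, seed=9)
        sel = pm.aic_select(self._fits(df, ("x1", "x2")))
        assert sel.chosen == "full"
        assert set(sel.table.columns) >= {"candidate", "aic", "aicc",
                                          "delta_aic", "chosen"}
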