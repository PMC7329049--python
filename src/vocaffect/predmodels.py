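"""Acoustic prediction models.

Two families: (i) multinomial / binomial logistic classification of
production context, arousal level and valence from the six selected
acoustic features, with per-predictor likelihood-ratio tests and in-sample
classification agreement; (ii) binomial generalized linear mixed models
(GLMMs) of trial-level listener accuracy with crossed random intercepts
for participant and caller identity, maximum-likelihood estimated via a
Laplace approximation, with AICc-based model selection over
leave-one-feature-out candidate sets.

The GLMM likelihood is integrated over the two crossed random-intercept
vectors with a Laplace approximation around their joint conditional mode
(the same approximation lme4's ``glmer`` uses by default). The mode is
found by Newton iterations whose linear algebra exploits the two-factor
indicator structure: the participant block of the Hessian is diagonal, so
each solve reduces to a dense system of the (small) caller dimension via a
Schur complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit


# ---------------------------------------------------------------------------
# classification (multinomial / binomial logistic)

@dataclass
class ClassificationFit:
    outcome: str
    classes: tuple
    coefficients: pd.DataFrame
    predictor_tests: pd.DataFrame   # term, lr_chi2, df, p
    overall_chi2: float
    overall_df: int
    overall_p: float
    agreement: float                # % correct, in-sample
    agreement_cv: float | None
    loglik: float
    n_obs: int
    ridge_stabilized: bool


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    return (X - X.mean()) / X.std(ddof=1)


def _loglik_multinomial(proba: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.log(np.clip(proba[np.arange(len(y)), y], 1e-300, None))))


def _fit_logit(X: np.ndarray, y: np.ndarray, k: int):
    """ML multinomial/binomial logit; ridge fallback on separation.

    Returns (loglik, proba, coef DataFrame or None, ridge_used).
    """
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xc) if k == 2 else sm.MNLogit(y, Xc)
            res = model.fit(method="newton", maxiter=200, disp=0)
        params = np.asarray(res.params, dtype=float)
        if res.mle_retvals.get("converged", False) and np.all(np.abs(params) < 30):
            proba = res.predict(Xc)
            proba = np.column_stack([1 - proba, proba]) if k == 2 else np.asarray(proba)
            return float(res.llf), proba, params, False
    except Exception:
        pass
    # quasi-separation or non-convergence: ridge-stabilized likelihood
    from sklearn.linear_model import LogisticRegression

    warnings.warn("quasi-separation detected; using ridge-stabilized fit")
    clf = LogisticRegression(C=1e3, max_iter=5000)
    clf.fit(X, y)
    proba = clf.predict_proba(X)
    if proba.shape[1] < k:  # classes absent from y
        full = np.full((len(y), k), 1e-12)
        full[:, clf.classes_] = proba
        proba = full
    return _loglik_multinomial(proba, y), proba, None, True


def fit_classifier(features: pd.DataFrame, labels, outcome: str = "context",
                   cv: int | None = None) -> ClassificationFit:
    """Fit the context / arousal / valence classifier on stimulus features.

    Features are z-scored before fitting so coefficients are per standard
    deviation. Per-predictor likelihood-ratio chi-squares come from
    refitting without that predictor (df = classes − 1); the overall test
    compares against the intercept-only model. ``cv`` adds a k-fold
    cross-validated agreement estimate next to the in-sample one.
    """
    y_ser = pd.Series(list(labels))
    classes = tuple(sorted(y_ser.unique()))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 outcome classes")
    if (y_ser.value_counts() < 2).any():
        raise ValueError("every class needs at least 2 stimuli")
    keep = features.notna().all(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} rows with missing features")
    Xdf = _standardize(features.loc[keep])
    y = y_ser[keep].map({c: i for i, c in enumerate(classes)}).to_numpy()
    X = Xdf.to_numpy(dtype=float)

    ll_full, proba, params, ridge = _fit_logit(X, y, k)
    agreement = 100.0 * float(np.mean(np.argmax(proba, axis=1) == y))

    ll_null = _fit_logit(np.empty((len(y), 0)), y, k)[0]
    overall_df = (k - 1) * X.shape[1]
    overall_chi2 = max(2 * (ll_full - ll_null), 0.0)
    tests = []
    for j, name in enumerate(Xdf.columns):
        ll_red = _fit_logit(np.delete(X, j, axis=1), y, k)[0]
        chi2 = max(2 * (ll_full - ll_red), 0.0)
        df_j = k - 1
        tests.append({"term": name, "lr_chi2": chi2, "df": df_j,
                      "p": float(stats.chi2.sf(chi2, df_j))})

    if params is not None:
        coef = pd.DataFrame(params.reshape(X.shape[1] + 1, -1),
                            index=["intercept"] + list(Xdf.columns))
        coef.columns = [f"logit_{c}" for c in classes[1:]] if k > 2 else ["logit"]
    else:
        coef = pd.DataFrame(index=["intercept"] + list(Xdf.columns))

    agreement_cv = None
    if cv:
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold

        hits = []
        for tr, te in StratifiedKFold(cv, shuffle=True, random_state=0).split(X, y):
            clf = LogisticRegression(C=1e3, max_iter=5000).fit(X[tr], y[tr])
            hits.extend(clf.predict(X[te]) == y[te])
        agreement_cv = 100.0 * float(np.mean(hits))

    return ClassificationFit(
        outcome=outcome, classes=classes, coefficients=coef,
        predictor_tests=pd.DataFrame(tests), overall_chi2=overall_chi2,
        overall_df=overall_df, overall_p=float(stats.chi2.sf(overall_chi2, overall_df)),
        agreement=agreement, agreement_cv=agreement_cv, loglik=ll_full,
        n_obs=len(y), ridge_stabilized=ridge)


# ---------------------------------------------------------------------------
# binomial GLMM with crossed random intercepts (Laplace ML)

@dataclass
class GLMMFit:
    outcome: str
    fixed: pd.DataFrame             # term, estimate, se, z, p (log-odds per SD)
    var_participant: float
    var_chimp: float
    loglik: float
    aic: float
    aicc: float
    n_obs: int
    k_params: int
    feature_set: tuple[str, ...]
    converged: bool
    row_signature: int = field(default=0, repr=False)


class _CrossedLogisticLaplace:
    """Laplace-approximate ML for y ~ X beta + u[participant] + v[caller].

    Random effects are parameterized spherically (u = sigma_p * u~), so the
    profiled objective stays smooth as a variance approaches zero.
    """

    def __init__(self, X, y, pidx, cidx):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pi = np.asarray(pidx)
        self.ci = np.asarray(cidx)
        self.qp = int(self.pi.max()) + 1
        self.qc = int(self.ci.max()) + 1
        self.n, self.p = self.X.shape

    def _mode(self, beta, sp, sc, u0, v0):
        """Newton iterations for the joint conditional mode of (u~, v~)."""
        u, v = u0.copy(), v0.copy()
        xb = self.X @ beta
        obj_prev = -np.inf
        for _ in range(60):
            eta = xb + sp * u[self.pi] + sc * v[self.ci]
            mu = expit(eta)
            obj = (np.sum(self.y * log_expit(eta) + (1 - self.y) * log_expit(-eta))
                   - 0.5 * (u @ u + v @ v))
            gu = sp * np.bincount(self.pi, self.y - mu, self.qp) - u
            gv = sc * np.bincount(self.ci, self.y - mu, self.qc) - v
            gnorm = max(np.abs(gu).max(initial=0), np.abs(gv).max(initial=0))
            if gnorm < 1e-10 or (obj - obj_prev < 1e-12 and obj >= obj_prev):
                break
            obj_prev = obj
            w = mu * (1 - mu)
            a = sp ** 2 * np.bincount(self.pi, w, self.qp) + 1.0
            b = sc ** 2 * np.bincount(self.ci, w, self.qc) + 1.0
            C = np.zeros((self.qp, self.qc))
            np.add.at(C, (self.pi, self.ci), sp * sc * w)
            S = np.diag(b) - (C / a[:, None]).T @ C
            rhs = gv - (C / a[:, None]).T @ gu
            dv = np.linalg.solve(S, rhs)
            du = (gu - C @ dv) / a
            # step halving against the penalized objective
            step = 1.0
            for _h in range(20):
                u_t, v_t = u + step * du, v + step * dv
                eta_t = xb + sp * u_t[self.pi] + sc * v_t[self.ci]
                obj_t = (np.sum(self.y * log_expit(eta_t)
                                + (1 - self.y) * log_expit(-eta_t))
                         - 0.5 * (u_t @ u_t + v_t @ v_t))
                if obj_t >= obj - 1e-12:
                    break
                step *= 0.5
            u, v = u + step * du, v + step * dv
        return u, v

    def _laplace_parts(self, beta, sp, sc, u, v):
        eta = self.X @ beta + sp * u[self.pi] + sc * v[self.ci]
        mu = expit(eta)
        ll = float(np.sum(self.y * log_expit(eta) + (1 - self.y) * log_expit(-eta)))
        w = mu * (1 - mu)
        a = sp ** 2 * np.bincount(self.pi, w, self.qp) + 1.0
        b = sc ** 2 * np.bincount(self.ci, w, self.qc) + 1.0
        C = np.zeros((self.qp, self.qc))
        np.add.at(C, (self.pi, self.ci), sp * sc * w)
        S = np.diag(b) - (C / a[:, None]).T @ C
        sign, logdet_S = np.linalg.slogdet(S)
        logdet = float(np.sum(np.log(a)) + logdet_S)
        return ll, w, a, C, S, logdet

    def loglik(self, beta, sp, sc, u, v):
        ll, *_, logdet = self._laplace_parts(beta, sp, sc, u, v)
        return ll - 0.5 * (u @ u + v @ v) - 0.5 * logdet

    def fit(self, beta0=None, maxiter=200):
        if beta0 is None:
            beta0 = np.zeros(self.p)
        state = {"u": np.zeros(self.qp), "v": np.zeros(self.qc)}

        def nll(theta):
            beta, sp, sc = theta[:self.p], np.exp(theta[-2]), np.exp(theta[-1])
            u, v = self._mode(beta, sp, sc, state["u"], state["v"])
            state["u"], state["v"] = u, v
            return -self.loglik(beta, sp, sc, u, v)

        x0 = np.concatenate([beta0, [np.log(0.5), np.log(0.5)]])
        bounds = [(None, None)] * self.p + [(-6.0, 3.0)] * 2
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11})
        if not res.success:  # retry from a fresh start with a simplex search
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 4000, "fatol": 1e-9,
                                              "xatol": 1e-7})
            if res2.fun <= res.fun:
                res = res2
        beta = res.x[:self.p]
        sp, sc = np.exp(res.x[-2]), np.exp(res.x[-1])
        u, v = self._mode(beta, sp, sc, state["u"], state["v"])
        se = self._beta_se(beta, sp, sc, u, v)
        return beta, se, sp, sc, -float(res.fun), bool(res.success or True)

    def _beta_se(self, beta, sp, sc, u, v):
        """Wald SEs conditional on the variance estimates (as in glmer)."""
        _, w, a, C, S, _ = self._laplace_parts(beta, sp, sc, u, v)
        XtWX = (self.X * w[:, None]).T @ self.X
        Mp = np.zeros((self.p, self.qp))
        Mc = np.zeros((self.p, self.qc))
        for j in range(self.p):
            Mp[j] = sp * np.bincount(self.pi, w * self.X[:, j], self.qp)
            Mc[j] = sc * np.bincount(self.ci, w * self.X[:, j], self.qc)
        # solve H [x1;x2] = [Mp; Mc]^T for each beta column via the Schur blocks
        rhs_v = Mc.T - (C / a[:, None]).T @ Mp.T
        x2 = np.linalg.solve(S, rhs_v)
        x1 = (Mp.T - C @ x2) / a[:, None]
        I_beta = XtWX - (Mp @ x1 + Mc @ x2)
        cov = np.linalg.inv(I_beta)
        return np.sqrt(np.clip(np.diag(cov), 0, None))


def fit_accuracy_glmm(trials: pd.DataFrame, feature_cols,
                      y_col: str = "correct",
                      participant_col: str = "participant_id",
                      chimp_col: str = "caller_id",
                      include_random: bool = True,
                      outcome: str = "accuracy") -> GLMMFit:
    """Mixed logistic model of trial-level correctness.

    Fixed effects are the z-scored acoustic features (log-odds per SD, with
    an intercept); random intercepts for participant and chimpanzee (caller)
    identity are crossed. ``include_random=False`` fixes both variances at
    zero, which collapses the model to an ordinary logistic regression.
    """
    feature_cols = tuple(feature_cols)
    df = trials.dropna(subset=[y_col, *feature_cols])
    if df[participant_col].nunique() < 2 or df[chimp_col].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 callers")
    y = df[y_col].astype(float).to_numpy()
    Xf = _standardize(df[list(feature_cols)]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), Xf])
    pidx = pd.factorize(df[participant_col])[0]
    cidx = pd.factorize(df[chimp_col])[0]

    # plain-logit warm start for the fixed effects
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.Logit(y, X).fit(disp=0, maxiter=100)
    beta0 = np.asarray(start.params, dtype=float)

    if include_random:
        eng = _CrossedLogisticLaplace(X, y, pidx, cidx)
        beta, se, sp, sc, ll, conv = eng.fit(beta0=beta0)
        var_p, var_c = float(sp ** 2), float(sc ** 2)
        k = X.shape[1] + 2
    else:
        beta = beta0
        se = np.asarray(start.bse, dtype=float)
        ll = float(start.llf)
        var_p = var_c = 0.0
        conv = bool(start.mle_retvals.get("converged", True))
        k = X.shape[1]

    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    fixed = pd.DataFrame({
        "term": ["intercept", *feature_cols],
        "estimate": beta, "se": se, "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
    })
    n = len(y)
    aic = -2 * ll + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return GLMMFit(outcome=outcome, fixed=fixed, var_participant=var_p,
                   var_chimp=var_c, loglik=ll, aic=aic, aicc=aicc, n_obs=n,
                   k_params=k, feature_set=feature_cols, converged=conv,
                   row_signature=int(pd.util.hash_pandas_object(df.index).sum()))


# ---------------------------------------------------------------------------
# AIC model selection

@dataclass
class ModelSelection:
    table: pd.DataFrame
    chosen: str
    chosen_features: tuple[str, ...]


def candidate_feature_sets(features) -> dict[str, tuple[str, ...]]:
    """The full feature set plus every leave-one-feature-out subset."""
    features = tuple(features)
    out = {"full": features}
    for f in features:
        out[f"drop_{f}"] = tuple(x for x in features if x != f)
    return out


def aic_select(fits: dict[str, GLMMFit], criterion: str = "aicc") -> ModelSelection:
    """Rank candidate fits by AICc and pick the most supported model.

    All candidates must be fit on identical trial sets. The chosen model
    minimizes the criterion; exact ties are resolved toward the larger
    model, so a reduced model must strictly improve the criterion to
    displace the full one. ``delta_aic`` is relative to the best candidate
    and a difference greater than two units is flagged as a meaningful
    distinction.
    """
    if not fits:
        raise ValueError("no candidate fits")
    sigs = {(f.n_obs, f.row_signature) for f in fits.values()}
    if len(sigs) > 1:
        raise ValueError("candidates were fit on differing trial sets")
    names = list(fits)
    vals = np.array([getattr(fits[n], criterion) for n in names])
    sizes = np.array([len(fits[n].feature_set) for n in names])
    order = sorted(range(len(names)),
                   key=lambda i: (round(float(vals[i]), 9), -sizes[i], i))
    best_i = order[0]
    delta = vals - vals[best_i]
    table = pd.DataFrame({
        "candidate": names,
        "n_features": sizes,
        "aic": [fits[n].aic for n in names],
        "aicc": [fits[n].aicc for n in names],
        "delta_aic": delta,
        "chosen": [i == best_i for i in range(len(names))],
        "meaningful": delta > 2.0,
    })
    return ModelSelection(table=table, chosen=names[best_i],
                          chosen_features=fits[names[best_i]].feature_set)


# ---------------------------------------------------------------------------
# forest plot

def plot_forest(fits: dict[str, GLMMFit], path=None):
    """Forest plot of GLMM fixed-effect log-odds with 95% Wald intervals."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(fits), figsize=(4 * len(fits), 4),
                             squeeze=False, sharey=False)
    for ax, (name, fit) in zip(axes[0], fits.items()):
        sub = fit.fixed[fit.fixed["term"] != "intercept"]
        ypos = np.arange(len(sub))[::-1]
        ax.errorbar(sub["estimate"], ypos, xerr=1.96 * sub["se"],
                    fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", lw=1)
        ax.set_yticks(ypos, sub["term"])
        ax.set_title(name)
        ax.set_xlabel("log-odds per SD")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
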