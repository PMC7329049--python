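"""Perceptual-accuracy statistics for the two listener experiments.

Experiment 1 (10-way forced choice + 5-point ratings): per-participant
confusion matrices, unbiased hit rates (Hu), Wagner chance levels, the
arcsine variance-stabilizing transform, paired Wilcoxon signed-rank tests
against chance, rating recoding/correctness, the negativity-bias and
fatigue checks. Experiment 2 (yes/no match-to-context): signal-detection
d′ with the 0.5/n extreme-rate adjustment and one-sample t-tests against
zero. Shared: outlier screening and the a-priori power analysis for a
one-sample/paired t-test via the noncentral t distribution.

The unbiased hit rate for category i is Hu_i = n_ii² / (row_i · col_i) —
the product of the hit rate and the precision — and its individual chance
level (Wagner) is row_i · col_i / N². Both are arcsine(sqrt(p))
transformed before testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

AROUSAL_LEVELS = ("high", "medium", "low")
VALENCE_LEVELS = ("positive", "negative")


# ---------------------------------------------------------------------------
# confusion matrices and unbiased hit rates

@dataclass
class ConfusionMatrix:
    """k_true x k_resp response counts for one participant."""

    counts: np.ndarray
    true_labels: tuple[str, ...]
    resp_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.true_labels), len(self.resp_labels)):
            raise ValueError("counts shape does not match labels")

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def diagonal(self) -> np.ndarray:
        """Count of matching (true label == response label) per true label."""
        resp_index = {lab: j for j, lab in enumerate(self.resp_labels)}
        return np.array([
            self.counts[i, resp_index[lab]] if lab in resp_index else 0
            for i, lab in enumerate(self.true_labels)])


def confusion_matrix(responses: pd.DataFrame, labels,
                     true_col: str = "true_context",
                     resp_col: str = "chosen_context",
                     resp_labels=None) -> ConfusionMatrix:
    """Tally one participant's true-category by response counts."""
    labels = tuple(labels)
    resp_labels = tuple(resp_labels) if resp_labels is not None else labels
    bad = set(responses[resp_col]) - set(resp_labels)
    if bad:
        raise ValueError(f"responses outside the category set: {sorted(bad)}")
    bad = set(responses[true_col]) - set(labels)
    if bad:
        raise ValueError(f"true labels outside the category set: {sorted(bad)}")
    ti = responses[true_col].map({l: i for i, l in enumerate(labels)}).to_numpy()
    ri = responses[resp_col].map({l: i for i, l in enumerate(resp_labels)}).to_numpy()
    counts = np.zeros((len(labels), len(resp_labels)), dtype=int)
    np.add.at(counts, (ti, ri), 1)
    return ConfusionMatrix(counts, labels, resp_labels)


def unbiased_hit_rate(cm: ConfusionMatrix) -> np.ndarray:
    """Hu_i = n_ii² / (row_i · col_i); 0 where a marginal is empty."""
    diag = cm.diagonal().astype(float)
    resp_index = {lab: j for j, lab in enumerate(cm.resp_labels)}
    col = np.array([cm.col_marginals[resp_index[lab]] if lab in resp_index else 0
                    for lab in cm.true_labels], dtype=float)
    denom = cm.row_marginals * col
    with np.errstate(divide="ignore", invalid="ignore"):
        hu = np.where(denom > 0, diag ** 2 / denom, 0.0)
    return hu


def wagner_chance(cm: ConfusionMatrix) -> np.ndarray:
    """Individual chance level: row_i · col_i / N²."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    resp_index = {lab: j for j, lab in enumerate(cm.resp_labels)}
    col = np.array([cm.col_marginals[resp_index[lab]] if lab in resp_index else 0
                    for lab in cm.true_labels], dtype=float)
    return cm.row_marginals * col / cm.n ** 2


def arcsine_transform(p):
    """arcsin(sqrt(p)), the variance stabilizer for proportions."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def hu_table(responses: pd.DataFrame, labels,
             true_col: str = "true_context",
             resp_col: str = "chosen_context",
             resp_labels=None) -> pd.DataFrame:
    """Per-participant, per-category Hu and chance (raw and arcsine).

    ``responses`` must carry ``participant_id`` plus the true/response
    columns; returns one row per participant x category.
    """
    rows = []
    for pid, grp in responses.groupby("participant_id", sort=True):
        cm = confusion_matrix(grp, labels, true_col, resp_col, resp_labels)
        hu = unbiased_hit_rate(cm)
        ch = wagner_chance(cm)
        for lab, h, c in zip(cm.true_labels, hu, ch):
            rows.append({"participant_id": pid, "category": lab,
                         "hu": h, "chance": c,
                         "hu_arcsine": math.asin(math.sqrt(h)),
                         "chance_arcsine": math.asin(math.sqrt(c))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signed-rank testing

def signed_rank_test(diffs, *, exact_max_n: int = 25):
    """Paired Wilcoxon signed-rank on a vector of differences.

    Zero differences are dropped (Wilcoxon's original policy). The exact
    null distribution is used for n <= ``exact_max_n`` when the absolute
    differences are tie-free; otherwise the normal approximation with
    continuity correction. All-zero input returns p = 1 by convention.
    Returns (statistic, p, n_effective).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        log.info("signed-rank: all differences zero; p = 1 by convention")
        return 0.0, 1.0, 0
    tie_free = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= exact_max_n and tie_free) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         method=method)
    return float(res.statistic), float(res.pvalue), int(d.size)


def wilcoxon_vs_chance(hu_table_df: pd.DataFrame, alpha: float = 0.05,
                       value_col: str = "hu_arcsine",
                       chance_col: str = "chance_arcsine") -> pd.DataFrame:
    """Per-category paired signed-rank of arcsine Hu against arcsine chance.

    Bonferroni-corrects ``alpha`` by the number of categories tested.
    """
    cats = list(dict.fromkeys(hu_table_df["category"]))
    alpha_corr = alpha / len(cats)
    rows = []
    for cat in cats:
        sub = hu_table_df[hu_table_df["category"] == cat]
        if len(sub) < 5:
            raise ValueError(f"category {cat}: need >= 5 paired values")
        stat, p, n_eff = signed_rank_test(
            sub[value_col].to_numpy() - sub[chance_col].to_numpy())
        rows.append({"category": cat, "statistic": stat, "p": p,
                     "n_effective": n_eff, "alpha_corrected": alpha_corr,
                     "significant": p < alpha_corr,
                     "mean_hu": sub["hu"].mean() if "hu" in sub else np.nan,
                     "mean_chance": sub["chance"].mean() if "chance" in sub else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rating recoding and correctness

def recode_and_score_ratings(ratings, truth_classes, kind: str,
                             participant_ids=None) -> pd.DataFrame:
    """Recode 1–5 ratings to −2..+2 and score per-response correctness.

    Arousal: correct iff value > 0 for high, < 0 for low, = 0 for medium.
    Valence: correct iff value > 0 for positive, < 0 for negative; stimuli
    with no specific valence are excluded (logged). ``participant_ids``,
    when given, are carried through the row filtering.
    """
    if kind not in ("arousal", "valence"):
        raise ValueError("kind must be 'arousal' or 'valence'")
    df = pd.DataFrame({"rating": np.asarray(ratings, dtype=float),
                       "truth_class": list(truth_classes)})
    if participant_ids is not None:
        df["participant_id"] = list(participant_ids)
    if not df["rating"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("ratings must be integers 1..5")
    missing = df["truth_class"].isna()
    if kind == "valence":
        missing |= df["truth_class"] == "none"
    if missing.any():
        log.info("excluding %d rows without a scoreable %s class",
                 int(missing.sum()), kind)
        df = df[~missing].copy()
    df["value"] = df["rating"].astype(int) - 3
    v = df["value"]
    if kind == "arousal":
        df["correct"] = ((v > 0) & (df["truth_class"] == "high")
                         | (v < 0) & (df["truth_class"] == "low")
                         | (v == 0) & (df["truth_class"] == "medium"))
    else:
        df["correct"] = ((v > 0) & (df["truth_class"] == "positive")
                         | (v < 0) & (df["truth_class"] == "negative"))
    return df


def rating_response_class(values, kind: str) -> pd.Series:
    """Map recoded rating values to response classes by sign."""
    v = np.asarray(values)
    if kind == "arousal":
        return pd.Series(np.where(v > 0, "high", np.where(v < 0, "low", "medium")))
    return pd.Series(np.where(v > 0, "positive",
                              np.where(v < 0, "negative", "neutral")))


def hu_from_ratings(scored: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Per-participant Hu/chance for the rating scales.

    Builds a true-class by response-class contingency table per participant
    (responses classed by rating sign, so valence has a third 'neutral'
    response column) and applies the Hu and Wagner-chance formulas.
    """
    true_labels = AROUSAL_LEVELS if kind == "arousal" else VALENCE_LEVELS
    resp_labels = AROUSAL_LEVELS if kind == "arousal" else ("positive", "negative", "neutral")
    df = scored.copy()
    df["resp_class"] = rating_response_class(df["value"].to_numpy(), kind).to_numpy()
    return hu_table(df, true_labels, true_col="truth_class",
                    resp_col="resp_class", resp_labels=resp_labels)


def valence_bias(scored_valence: pd.DataFrame):
    """Mean recoded valence rating per participant, tested against zero.

    A significantly negative mean indicates a bias toward judging the
    vocalizations as negative. Returns (per-participant means, result dict).
    """
    means = scored_valence.groupby("participant_id")["value"].mean()
    stat, p, n_eff = signed_rank_test(means.to_numpy())
    return means, {"mean": float(means.mean()), "sd": float(means.std(ddof=1)),
                   "statistic": stat, "p": p, "n": len(means),
                   "n_effective": n_eff}


def fatigue_check(scored_trials: pd.DataFrame, window: int = 30,
                  judgment_cols=("context", "arousal", "valence")) -> pd.DataFrame:
    """Accuracy in the first vs the last ``window`` trials per participant.

    ``scored_trials`` needs ``participant_id``, ``trial_index`` and one
    boolean ``correct_<type>`` column per judgment type (NaN rows, e.g.
    valence of no-valence stimuli, are ignored in the means).
    """
    if "trial_index" not in scored_trials:
        raise ValueError("trial_index column required")
    n_trials = scored_trials.groupby("participant_id")["trial_index"].max()
    if (n_trials < 2 * window).any():
        raise ValueError(f"every participant needs >= {2 * window} ordered trials")
    rows = []
    for kind in judgment_cols:
        col = f"correct_{kind}"
        early, late = [], []
        for pid, grp in scored_trials.groupby("participant_id", sort=True):
            grp = grp.sort_values("trial_index")
            last_start = grp["trial_index"].max() - window
            early.append(grp.loc[grp["trial_index"] <= window, col].mean())
            late.append(grp.loc[grp["trial_index"] > last_start, col].mean())
        early, late = np.asarray(early, float), np.asarray(late, float)
        stat, p, n_eff = signed_rank_test(early - late)
        rows.append({"judgment": kind, "mean_early": early.mean(),
                     "mean_late": late.mean(), "statistic": stat, "p": p,
                     "n_effective": n_eff})
    return pd.DataFrame(rows)


def score_exp1_responses(responses: pd.DataFrame,
                         stimuli: pd.DataFrame) -> pd.DataFrame:
    """Join experiment-1 responses with stimulus truth and score each trial.

    Adds ``true_context``, ``caller_id``, recoded rating values and three
    per-trial correctness columns: ``correct_context`` (chosen category
    matches the production context), ``correct_arousal`` and
    ``correct_valence`` (rating sign matches the class; NaN for stimuli
    with no specific valence).
    """
    truth = stimuli[["stimulus_id", "caller_id", "context_id",
                     "arousal", "valence"]].rename(
        columns={"context_id": "true_context"})
    df = responses.merge(truth, on="stimulus_id", how="left", validate="m:1")
    df["arousal_value"] = df["arousal_rating"].astype(int) - 3
    df["valence_value"] = df["valence_rating"].astype(int) - 3
    df["correct_context"] = df["chosen_context"] == df["true_context"]
    av = df["arousal_value"]
    df["correct_arousal"] = ((av > 0) & (df["arousal"] == "high")
                             | (av < 0) & (df["arousal"] == "low")
                             | (av == 0) & (df["arousal"] == "medium"))
    vv = df["valence_value"]
    correct_val = ((vv > 0) & (df["valence"] == "positive")
                   | (vv < 0) & (df["valence"] == "negative")).astype(float)
    correct_val[df["valence"] == "none"] = np.nan
    df["correct_valence"] = correct_val
    return df


# ---------------------------------------------------------------------------
# signal detection (experiment 2)

@dataclass
class SDTResult:
    n_signal: int
    n_noise: int
    hit_rate: float
    fa_rate: float
    hit_adj: float
    fa_adj: float
    dprime: float


def _adjust_rate(p: float, n: int) -> float:
    if p <= 0.0:
        return 0.5 / n
    if p >= 1.0:
        return (n - 0.5) / n
    return p


def dprime(responses: pd.DataFrame, participant=None) -> SDTResult:
    """d′ = z(hit_adj) − z(fa_adj) for one participant's yes/no trials.

    Extreme rates (0 or 1) are replaced by 0.5/n and (n−0.5)/n with n the
    participant's own signal (or noise) trial count before z-transforming.
    """
    df = responses
    if participant is not None:
        df = df[df["participant_id"] == participant]
    sig = df[df["is_match"].astype(bool)]
    noi = df[~df["is_match"].astype(bool)]
    if len(sig) == 0 or len(noi) == 0:
        raise ValueError("need at least one signal and one noise trial")
    hit = float(sig["response_yes"].mean())
    fa = float(noi["response_yes"].mean())
    hit_adj = _adjust_rate(hit, len(sig))
    fa_adj = _adjust_rate(fa, len(noi))
    d = float(stats.norm.ppf(hit_adj) - stats.norm.ppf(fa_adj))
    return SDTResult(len(sig), len(noi), hit, fa, hit_adj, fa_adj, d)


def dprime_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SDT summary over an experiment-2 response table."""
    rows = []
    for (pid, ctx), grp in responses.groupby(
            ["participant_id", "condition_context"], sort=True):
        r = dprime(grp)
        rows.append({"participant_id": pid, "condition_context": ctx,
                     **r.__dict__})
    return pd.DataFrame(rows)


def dprime_vs_chance(dprime_df: pd.DataFrame,
                     alpha: float = 0.005) -> pd.DataFrame:
    """One-sample t-tests of per-participant d′ against zero, per context."""
    rows = []
    for ctx, grp in dprime_df.groupby("condition_context", sort=True):
        d = grp["dprime"].to_numpy(dtype=float)
        if d.size < 2:
            raise ValueError(f"context {ctx}: need >= 2 participants")
        if np.allclose(d.std(ddof=1), 0):
            rows.append({"condition_context": ctx, "mean_dprime": d.mean(),
                         "t": np.nan, "p": np.nan, "ci_low": d.mean(),
                         "ci_high": d.mean(), "n": d.size,
                         "significant": False, "zero_variance": True})
            continue
        res = stats.ttest_1samp(d, 0.0)
        lo, hi = res.confidence_interval(0.95)
        rows.append({"condition_context": ctx, "mean_dprime": float(d.mean()),
                     "t": float(res.statistic), "p": float(res.pvalue),
                     "ci_low": float(lo), "ci_high": float(hi), "n": d.size,
                     "significant": res.pvalue < alpha, "zero_variance": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# valence contrasts, outliers, power

def valence_accuracy_contrast(scores: pd.DataFrame, design: str) -> dict:
    """Negative- vs positive-context accuracy.

    ``design='exp1'``: paired signed-rank on per-participant accuracy
    (columns ``participant_id``, ``valence``, ``value`` where value is the
    arcsine Hu or similar per-participant score). ``design='exp2'``:
    one-way ANOVA on d′ grouped by ``valence``. Reports the direction of
    the difference.
    """
    groups = set(scores["valence"])
    if not {"positive", "negative"} <= groups:
        raise ValueError("need both positive and negative scores")
    neg = scores.loc[scores["valence"] == "negative"]
    pos = scores.loc[scores["valence"] == "positive"]
    if design == "exp1":
        wide = scores.pivot_table(index="participant_id", columns="valence",
                                  values="value", aggfunc="mean")
        stat, p, n_eff = signed_rank_test(
            (wide["negative"] - wide["positive"]).to_numpy())
        mneg, mpos = wide["negative"].mean(), wide["positive"].mean()
    elif design == "exp2":
        f = stats.f_oneway(neg["value"].to_numpy(), pos["value"].to_numpy())
        stat, p = float(f.statistic), float(f.pvalue)
        mneg, mpos = neg["value"].mean(), pos["value"].mean()
    else:
        raise ValueError("design must be 'exp1' or 'exp2'")
    direction = ("negative > positive" if mneg > mpos
                 else "positive > negative" if mpos > mneg else "undefined")
    return {"design": design, "statistic": stat, "p": p,
            "mean_negative": float(mneg), "mean_positive": float(mpos),
            "direction": direction}


def screen_outliers(accuracy: pd.Series, n_sd: float = 3.0):
    """Flag participants scoring ``n_sd`` s.d. or more below the group mean.

    The threshold is computed once on the full sample. Returns
    (retained_index, excluded_index, threshold).
    """
    acc = accuracy.astype(float)
    if len(acc) < 3:
        raise ValueError("need >= 3 participants to screen")
    thr = acc.mean() - n_sd * acc.std(ddof=1)
    excluded = acc.index[acc <= thr] if acc.std(ddof=1) > 0 else acc.index[:0]
    if len(excluded):
        log.info("excluding %d participants below %.4f", len(excluded), thr)
    return acc.index.difference(excluded), excluded, float(thr)


def _t_power(n: int, d: float, alpha: float, tail: str) -> float:
    df = n - 1
    nc = d * math.sqrt(n)
    if tail == "one":
        crit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(crit, df, nc))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def power_n_ttest(effect_size_d: float, alpha: float, power: float,
                  tail: str = "one", max_n: int = 10_000_000) -> int:
    """Minimum n for a one-sample (or paired) t-test to reach target power.

    Searches the smallest integer n whose power — computed from the
    noncentral t distribution with noncentrality d·sqrt(n) and critical
    value at ``alpha`` with n−1 degrees of freedom — meets ``power``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    hi = 2
    while _t_power(hi, effect_size_d, alpha, tail) < power:
        hi *= 2
        if hi > max_n:
            raise ValueError(
                f"power {power} unattainable with d={effect_size_d}, "
                f"alpha={alpha} within n <= {max_n}")
    lo = max(hi // 2, 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if _t_power(mid, effect_size_d, alpha, tail) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)
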