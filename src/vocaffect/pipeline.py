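"""End-to-end orchestration: corpus → features → selection → statistics → models.

A run is fully determined by a :class:`RunConfig`; every stochastic stage
draws from a sub-seed derived deterministically from the master seed and
the stage name, so re-running any subset of stages against cached upstream
outputs reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, featsel, perceptstats, predmodels, synthcorpus

log = logging.getLogger(__name__)

STAGES = ("corpus", "features", "reduce", "exp1", "exp2", "models")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Defaults reproduce the study's design sizes: 310 participants in the
    categorization experiment and 312 per context (3120 total) in the
    match-to-context experiment, with the Bonferroni-corrected alpha levels
    used for the context and d′ tests.
    """

    out_dir: str = "out"
    seed: int = 1
    sample_rate: int = 44100
    listener_preset: str = "default"          # or "null"
    n_participants_exp1: int = 310
    n_participants_per_context_exp2: int = 312
    alpha_family: float = 0.05                # Bonferroni-divided across the 10 contexts
    alpha_dprime: float = 0.005
    alpha_other: float = 0.05
    fit_glmms: bool = True
    glmm_selection: bool = True               # leave-one-out AICc candidate scan
    acoustic: acoustics.AcousticConfig = field(default_factory=acoustics.AcousticConfig)

    def corpus_config(self) -> synthcorpus.CorpusConfig:
        return synthcorpus.paper_config(sample_rate=self.sample_rate)

    def listener(self) -> synthcorpus.ListenerModel:
        if self.listener_preset == "default":
            return synthcorpus.default_listener()
        if self.listener_preset == "null":
            return synthcorpus.null_listener()
        raise ValueError(f"unknown listener preset {self.listener_preset!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acoustic"] = dataclasses.asdict(self.acoustic)
        return d


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed; adding stages never shifts others."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    valid: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def validate_design(config: RunConfig) -> dict:
    """Report-only consistency checks of the configured design.

    Checks the corpus preset against the published per-context counts, the
    match-to-context arithmetic (each participant hears half of the
    condition's stimuli, so judgments per stimulus = participants / 2), and
    whether the configured sample sizes meet the a-priori power analysis.
    """
    corpus = config.corpus_config()
    n_stim = sum(p.n_stimuli for p in corpus.profiles)
    judgments = config.n_participants_per_context_exp2 / 2
    req_exp1 = perceptstats.power_n_ttest(0.2, 0.005, 0.80, "one")
    req_judgments = perceptstats.power_n_ttest(0.2, 0.05, 0.80, "one")
    return {
        "corpus_total": n_stim,
        "corpus_matches_preset": n_stim == synthcorpus.N_STIMULI_TOTAL,
        "n_callers": sum(p.caller_pool for p in corpus.profiles),
        "exp1_n": config.n_participants_exp1,
        "exp1_required_n": req_exp1,
        "exp1_powered": config.n_participants_exp1 >= req_exp1,
        "exp2_total_n": 10 * config.n_participants_per_context_exp2,
        "judgments_per_stimulus": judgments,
        "required_judgments_per_stimulus": req_judgments,
        "exp2_powered": judgments >= req_judgments,
        "exp2_feasible": judgments >= 1,
    }


class Pipeline:
    """Stage runner with CSV hand-off between stages."""

    def __init__(self, config: RunConfig):
        config_hash = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
        self.config = config
        self.out = Path(config.out_dir)
        self.manifest = RunManifest(config_hash=config_hash, seed=config.seed,
                                    version=__version__)

    # -- paths ------------------------------------------------------------
    def _p(self, *parts) -> Path:
        p = self.out.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def _read(self, *parts) -> pd.DataFrame:
        return pd.read_csv(self.out.joinpath(*parts))

    # -- stages -----------------------------------------------------------
    def stage_corpus(self) -> None:
        cfg = self.config
        stim_dir = self._p("stimuli", "x").parent
        stimuli = synthcorpus.generate_corpus(
            cfg.corpus_config(), stage_seed(cfg.seed, "corpus"), stim_dir)
        self.manifest.stages["corpus"] = {"completed": True,
                                          "rows": {"stimuli": len(stimuli)}}

    def stage_features(self) -> None:
        stimuli = self._read("stimuli", "stimuli.csv")
        feats = acoustics.extract_features_table(
            stimuli, self.out / "stimuli", self.config.acoustic)
        n_missing = int(feats.isna().any(axis=1).sum())
        if n_missing:
            log.info("%d stimuli have undefined voiced features", n_missing)
        feats.to_csv(self._p("features", "features.csv"), index=False)
        self.manifest.stages["features"] = {
            "completed": True,
            "rows": {"features": len(feats), "incomplete": n_missing}}

    def stage_reduce(self) -> None:
        feats = self._read("features", "features.csv").set_index("stimulus_id")
        pca = featsel.pca_varimax(feats)
        pca.loadings.to_csv(self._p("features", "pca_loadings.csv"))
        selected = featsel.select_features(pca, policy="replicate")
        vif_rep = featsel.vif(feats, list(selected))
        vif_rep.vif.rename("vif").to_csv(self._p("features", "vif.csv"))
        pd.Series(list(selected), name="feature").to_csv(
            self._p("features", "selected.csv"), index=False)
        self.manifest.stages["reduce"] = {
            "completed": True,
            "rows": {"loadings": len(pca.loadings),
                     "retained_components": len(pca.retained)},
            "variance_retained": float(np.sum(pca.variance_explained))}

    def stage_exp1(self) -> None:
        cfg = self.config
        stimuli = self._read("stimuli", "stimuli.csv")
        responses = synthcorpus.simulate_exp1(
            stimuli, cfg.n_participants_exp1, cfg.listener(),
            stage_seed(cfg.seed, "exp1"))
        responses.to_csv(self._p("exp1", "exp1_responses.csv"), index=False)
        scored = perceptstats.score_exp1_responses(responses, stimuli)

        acc = scored.groupby("participant_id")["correct_context"].mean()
        retained, excluded, thr = perceptstats.screen_outliers(acc)
        scored = scored[scored["participant_id"].isin(retained)]

        contexts = [p.context_id for p in cfg.corpus_config().profiles]
        hu_ctx = perceptstats.hu_table(scored, contexts)
        hu_ctx.to_csv(self._p("exp1", "hu_scores.csv"), index=False)
        tests = [perceptstats.wilcoxon_vs_chance(hu_ctx, cfg.alpha_family)
                 .assign(judgment="context")]

        hu_by_kind = {}
        for kind in ("arousal", "valence"):
            sc = perceptstats.recode_and_score_ratings(
                scored[f"{kind}_rating"], scored[kind], kind,
                participant_ids=scored["participant_id"])
            hu_k = perceptstats.hu_from_ratings(sc, kind)
            hu_by_kind[kind] = hu_k
            tests.append(perceptstats.wilcoxon_vs_chance(hu_k, cfg.alpha_other)
                         .assign(judgment=kind))
        pd.concat(tests, ignore_index=True).to_csv(
            self._p("exp1", "tests.csv"), index=False)

        scored_val = scored[scored["valence"] != "none"].rename(
            columns={"valence_value": "value"})
        means, bias = perceptstats.valence_bias(scored_val)
        fatigue = perceptstats.fatigue_check(scored)
        fatigue.to_csv(self._p("exp1", "fatigue.csv"), index=False)

        # negative vs positive arcsine-Hu contrast on the valence ratings
        hu_v = hu_by_kind["valence"].rename(columns={"category": "valence",
                                                     "hu_arcsine": "value"})
        contrast = perceptstats.valence_accuracy_contrast(hu_v, "exp1")
        with open(self._p("exp1", "summary.json"), "w") as fh:
            json.dump({"valence_bias": bias, "valence_contrast": contrast,
                       "outliers_excluded": len(excluded),
                       "outlier_threshold": thr}, fh, indent=2)
        self.manifest.stages["exp1"] = {
            "completed": True,
            "rows": {"responses": len(responses), "hu": len(hu_ctx),
                     "participants_retained": len(retained)}}

    def stage_exp2(self) -> None:
        cfg = self.config
        stimuli = self._read("stimuli", "stimuli.csv")
        listener = cfg.listener()
        parts = []
        for prof in cfg.corpus_config().profiles:
            parts.append(synthcorpus.simulate_exp2(
                stimuli, prof.context_id,
                cfg.n_participants_per_context_exp2, listener,
                stage_seed(cfg.seed, f"exp2:{prof.context_id}")))
        for i, df in enumerate(parts):  # participant ids unique across conditions
            df["participant_id"] = df["participant_id"] + f"_{df['condition_context'].iloc[0]}"
        responses = pd.concat(parts, ignore_index=True)
        responses.to_csv(self._p("exp2", "exp2_responses.csv"), index=False)

        dp = perceptstats.dprime_table(responses)
        dp.to_csv(self._p("exp2", "dprime.csv"), index=False)
        tests = perceptstats.dprime_vs_chance(dp, cfg.alpha_dprime)
        tests.to_csv(self._p("exp2", "dprime_tests.csv"), index=False)

        valence_of = {p.context_id: p.valence_class
                      for p in cfg.corpus_config().profiles}
        dp_v = dp.assign(valence=dp["condition_context"].map(valence_of),
                         value=dp["dprime"])
        contrast = perceptstats.valence_accuracy_contrast(
            dp_v[dp_v["valence"] != "none"], "exp2")
        with open(self._p("exp2", "summary.json"), "w") as fh:
            json.dump({"valence_contrast": contrast}, fh, indent=2)
        self.manifest.stages["exp2"] = {
            "completed": True,
            "rows": {"responses": len(responses), "participants": dp.shape[0]}}

    def stage_models(self) -> None:
        cfg = self.config
        stimuli = self._read("stimuli", "stimuli.csv")
        feats = self._read("features", "features.csv")
        selected = tuple(self._read("features", "selected.csv")["feature"])
        table = stimuli.merge(feats, on="stimulus_id")
        complete = table.dropna(subset=list(selected))

        cls_rows = []
        fits = {}
        for outcome, label_col in (("context", "context_id"),
                                   ("arousal", "arousal"),
                                   ("valence", "valence")):
            sub = complete if outcome != "valence" else complete[
                complete["valence"] != "none"]
            fit = predmodels.fit_classifier(sub[list(selected)],
                                            sub[label_col], outcome)
            fits[outcome] = fit
            for _, row in fit.predictor_tests.iterrows():
                cls_rows.append({"outcome": outcome, **row.to_dict(),
                                 "agreement": fit.agreement,
                                 "overall_chi2": fit.overall_chi2,
                                 "overall_p": fit.overall_p})
        pd.DataFrame(cls_rows).to_csv(
            self._p("models", "classification_fits.csv"), index=False)
        rows = {"classification": len(cls_rows)}

        if cfg.fit_glmms:
            glmm_fits, sel_rows, fit_rows = {}, [], []
            for outcome, trials in self._glmm_trial_tables(
                    stimuli, complete, selected).items():
                cands = (predmodels.candidate_feature_sets(selected)
                         if cfg.glmm_selection else {"full": selected})
                fits_o = {name: predmodels.fit_accuracy_glmm(
                              trials, fs, outcome=outcome)
                          for name, fs in cands.items()}
                sel = predmodels.aic_select(fits_o)
                glmm_fits[outcome] = fits_o[sel.chosen]
                for _, r in sel.table.assign(outcome=outcome).iterrows():
                    sel_rows.append(r.to_dict())
                for _, r in fits_o[sel.chosen].fixed.iterrows():
                    fit_rows.append({"outcome": outcome, **r.to_dict(),
                                     "var_participant": fits_o[sel.chosen].var_participant,
                                     "var_chimp": fits_o[sel.chosen].var_chimp,
                                     "aicc": fits_o[sel.chosen].aicc})
            pd.DataFrame(fit_rows).to_csv(
                self._p("models", "glmm_fits.csv"), index=False)
            pd.DataFrame(sel_rows).to_csv(
                self._p("models", "model_selection.csv"), index=False)
            predmodels.plot_forest(glmm_fits, self._p("models", "forest.svg"))
            rows["glmm_terms"] = len(fit_rows)
        self.manifest.stages["models"] = {"completed": True, "rows": rows}

    def _glmm_trial_tables(self, stimuli, feature_table, selected) -> dict:
        """Per-outcome trial tables joining correctness with stimulus features."""
        out = {}
        exp1_path = self.out / "exp1" / "exp1_responses.csv"
        if exp1_path.exists():
            scored = perceptstats.score_exp1_responses(
                pd.read_csv(exp1_path), stimuli)
            scored = scored.merge(
                feature_table[["stimulus_id", *selected]], on="stimulus_id")
            out["arousal"] = scored.rename(
                columns={"correct_arousal": "correct"})[
                ["participant_id", "caller_id", "correct", *selected]]
            val = scored[scored["valence"] != "none"]
            out["valence"] = val.rename(
                columns={"correct_valence": "correct"})[
                ["participant_id", "caller_id", "correct", *selected]]
        exp2_path = self.out / "exp2" / "exp2_responses.csv"
        if exp2_path.exists():
            resp = pd.read_csv(exp2_path)
            resp["correct"] = resp["response_yes"] == resp["is_match"]
            stim_feats = stimuli[["stimulus_id", "caller_id"]].merge(
                feature_table[["stimulus_id", *selected]], on="stimulus_id")
            trials = resp.merge(stim_feats, on="stimulus_id")
            out["context_match"] = trials.dropna(subset=list(selected))[
                ["participant_id", "caller_id", "correct", *selected]]
        return out

    # -- driver -----------------------------------------------------------
    def run(self, stages=STAGES) -> RunManifest:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                self.manifest.valid = False
                self.manifest.stages[stage] = {"completed": False}
                self._write_manifest()
                log.error("stage %r failed", stage)
                raise
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        self._p("manifest.json").write_text(self.manifest.to_json())


def run_all(config: RunConfig, stages=STAGES) -> RunManifest:
    """Execute the pipeline (or a contiguous tail of it) under ``config``.

    Validation failures abort before any stage runs; a failing stage marks
    the manifest invalid and re-raises with the stage named in the log.
    """
    if config.n_participants_exp1 < 1 or config.n_participants_per_context_exp2 < 1:
        raise ValueError("participant counts must be >= 1")
    config.corpus_config().validate()
    return Pipeline(config).run(stages)
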