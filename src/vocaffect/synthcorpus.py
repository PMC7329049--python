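"""Synthetic stimulus corpus and simulated listeners.

This module builds a fully synthetic stand-in for a playback-experiment
corpus of chimpanzee call bouts: 155 stimuli from 66 callers across 10
behavioural contexts (each context carrying an arousal class and a valence
class), plus simulators for the two listener tasks downstream statistics
expect — a 10-way forced-choice categorization with 5-point arousal and
valence ratings (experiment 1) and a yes/no match-to-context task
(experiment 2).

Every waveform is synthesized from a harmonic source (12 harmonics with a
configurable spectral tilt) mixed with Gaussian noise, so the acoustic axes
the analysis measures — fundamental frequency, harmonics-to-noise ratio,
spectral balance, bout timing — are all controlled by known parameters and
can serve as oracles in tests. The synthetic calls make no claim to
perceptual realism; they exist so that every downstream stage is testable
without any audio download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.special import expit
from scipy.stats import norm

AROUSAL_CLASSES = ("high", "medium", "low")
VALENCE_CLASSES = ("positive", "negative", "none")


@dataclass(frozen=True)
class SynthesisParams:
    """Distribution parameters for one context's call-bout generator.

    Units: frequencies in Hz, durations in seconds, spectral tilt in
    dB/octave. ``noise_fraction`` is the fraction of signal *power*
    contributed by broadband noise (0 = pure harmonic, 1 = pure noise).
    """

    f0_base_mean: float
    f0_base_sd: float
    f0_mod_depth: float
    noise_fraction: float
    n_calls_range: tuple[int, int]
    call_dur_range: tuple[float, float]
    silence_range: tuple[float, float]
    spectral_tilt_db: float


@dataclass(frozen=True)
class ContextProfile:
    """Design row for one behavioural context."""

    context_id: str
    label: str
    valence_class: str
    arousal_class: str
    n_stimuli: int
    caller_pool: int
    synthesis: SynthesisParams

    def __post_init__(self) -> None:
        if self.valence_class not in VALENCE_CLASSES:
            raise ValueError(f"unknown valence class {self.valence_class!r}")
        if self.arousal_class not in AROUSAL_CLASSES:
            raise ValueError(f"unknown arousal class {self.arousal_class!r}")
        if self.caller_pool > self.n_stimuli:
            raise ValueError(
                f"{self.context_id}: caller_pool ({self.caller_pool}) exceeds "
                f"n_stimuli ({self.n_stimuli})"
            )


def _sp(f0, sd, mod, noise, calls, dur, sil, tilt) -> SynthesisParams:
    return SynthesisParams(f0, sd, mod, noise, calls, dur, sil, tilt)


#: The replicate-study corpus design: per-context stimulus counts sum to 155,
#: arousal marginals are high 62 / medium 71 / low 22, and caller pools are
#: disjoint integers in [4, 21] summing to 66. Context ids c1..c10 follow the
#: ordering used for the confusion-matrix axes. The synthesis presets order
#: the contexts acoustically (screams high-pitched, long and loud; grunts
#: low-pitched, short and noisy) so that negative / high-arousal contexts are
#: acoustically more extreme; they are presets, not claims about chimpanzees.
PAPER_CONTEXTS: tuple[ContextProfile, ...] = (
    ContextProfile("c1", "eating high value food", "positive", "medium", 19, 8,
                   _sp(150, 30, 0.06, 0.45, (3, 6), (0.15, 0.35), (0.08, 0.25), -12.0)),
    ContextProfile("c2", "eating low value food", "positive", "low", 22, 9,
                   _sp(120, 25, 0.05, 0.50, (2, 5), (0.12, 0.30), (0.10, 0.30), -13.0)),
    ContextProfile("c3", "copulating", "none", "medium", 11, 5,
                   _sp(350, 60, 0.10, 0.30, (2, 5), (0.20, 0.50), (0.10, 0.30), -9.0)),
    ContextProfile("c4", "being separated from mother", "negative", "medium", 10, 4,
                   _sp(420, 70, 0.12, 0.25, (2, 5), (0.20, 0.45), (0.10, 0.30), -9.0)),
    ContextProfile("c5", "discovering a large food source", "positive", "high", 12, 5,
                   _sp(450, 80, 0.10, 0.20, (4, 8), (0.20, 0.50), (0.08, 0.20), -8.0)),
    ContextProfile("c6", "being refused access to food", "negative", "medium", 15, 6,
                   _sp(700, 120, 0.12, 0.35, (3, 6), (0.30, 0.70), (0.08, 0.20), -6.0)),
    ContextProfile("c7", "being tickled", "positive", "medium", 16, 7,
                   _sp(250, 50, 0.08, 0.50, (4, 8), (0.10, 0.30), (0.06, 0.15), -10.0)),
    ContextProfile("c8", "being attacked by another chimpanzee", "negative", "high", 21, 9,
                   _sp(1100, 180, 0.12, 0.30, (3, 7), (0.40, 0.90), (0.06, 0.15), -4.0)),
    ContextProfile("c9", "threatening an aggressive chimp or predator", "negative", "high", 16, 7,
                   _sp(600, 100, 0.10, 0.40, (2, 5), (0.25, 0.60), (0.08, 0.20), -6.0)),
    ContextProfile("c10", "discovering something scary", "negative", "high", 13, 6,
                   _sp(500, 90, 0.10, 0.50, (2, 4), (0.15, 0.40), (0.10, 0.25), -7.0)),
)

N_STIMULI_TOTAL = 155
N_CALLERS_TOTAL = 66
CONTEXT_IDS = tuple(p.context_id for p in PAPER_CONTEXTS)


@dataclass(frozen=True)
class CorpusConfig:
    profiles: tuple[ContextProfile, ...] = PAPER_CONTEXTS
    sample_rate: int = 44100
    peak_target: float = 0.9
    replicate_paper: bool = True

    def validate(self) -> None:
        total = sum(p.n_stimuli for p in self.profiles)
        if self.replicate_paper and total != N_STIMULI_TOTAL:
            raise ValueError(
                f"replicate-paper preset requires {N_STIMULI_TOTAL} stimuli, "
                f"config sums to {total}"
            )
        if self.replicate_paper:
            pools = [p.caller_pool for p in self.profiles]
            if sum(pools) != N_CALLERS_TOTAL:
                raise ValueError(
                    f"replicate-paper preset requires {N_CALLERS_TOTAL} callers, "
                    f"pools sum to {sum(pools)}"
                )
            if any(not (4 <= c <= 21) for c in pools):
                raise ValueError("caller pools must lie in [4, 21]")
        if not 0 < self.peak_target <= 1:
            raise ValueError("peak_target must be in (0, 1]")


def paper_config(sample_rate: int = 44100) -> CorpusConfig:
    """The replicate-study corpus configuration."""
    return CorpusConfig(sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# waveform synthesis

def synthesize_call_bout(
    f0_hz: float,
    call_durations,
    silence_durations=None,
    *,
    noise_fraction=0.0,
    spectral_tilt_db: float = -10.0,
    f0_mod_depth: float = 0.0,
    f0_mod_rate: float = 3.0,
    f0_call_scale=None,
    n_harmonics: int = 12,
    ramp_s: float = 0.01,
    sample_rate: int = 44100,
    rng=None,
) -> np.ndarray:
    """Synthesize one call bout as a float waveform.

    The bout is a concatenation of amplitude-enveloped call segments
    separated by silences. Each call is a stack of ``n_harmonics`` harmonics
    of a (possibly sinusoidally modulated) f0 contour, with per-harmonic
    amplitudes rolled off at ``spectral_tilt_db`` dB/octave, mixed with
    Gaussian noise so that noise carries ``noise_fraction`` of the power.
    ``noise_fraction`` and ``f0_call_scale`` may be scalars or one value
    per call, allowing within-bout heterogeneity in noisiness and pitch.
    Hann on/off ramps of ``ramp_s`` avoid clicks at call edges.

    Deterministic for a given ``rng`` state (pass ``np.random.default_rng(seed)``).
    """
    rng = np.random.default_rng(rng)
    call_durations = np.atleast_1d(np.asarray(call_durations, dtype=float))
    n_calls = call_durations.size
    if n_calls < 1:
        raise ValueError("a bout needs at least one call")
    if np.any(call_durations <= 0):
        raise ValueError("call durations must be positive")
    if f0_hz <= 0:
        raise ValueError("f0 must be positive")
    noise_fraction = np.broadcast_to(
        np.asarray(noise_fraction, dtype=float), (n_calls,))
    if np.any((noise_fraction < 0) | (noise_fraction > 1)):
        raise ValueError("noise_fraction must lie in [0, 1]")
    if f0_call_scale is None:
        f0_call_scale = 1.0
    f0_call_scale = np.broadcast_to(
        np.asarray(f0_call_scale, dtype=float), (n_calls,))
    if silence_durations is None:
        silence_durations = []
    silence_durations = np.atleast_1d(np.asarray(silence_durations, dtype=float))
    if silence_durations.size != n_calls - 1:
        raise ValueError("need exactly n_calls - 1 silences")

    pieces = []
    for i, dur in enumerate(call_durations):
        n = max(int(round(dur * sample_rate)), 2)
        t = np.arange(n) / sample_rate
        nf = float(noise_fraction[i])
        f0_call = f0_hz * float(f0_call_scale[i])
        if nf < 1.0:
            f0_t = f0_call * (1.0 + f0_mod_depth
                              * np.sin(2 * np.pi * f0_mod_rate * t
                                       + rng.uniform(0, 2 * np.pi)))
            phase = 2 * np.pi * np.cumsum(f0_t) / sample_rate
            harm = np.zeros(n)
            for h in range(1, n_harmonics + 1):
                if h * f0_call >= 0.5 * sample_rate:  # keep below Nyquist
                    break
                amp = 10.0 ** (spectral_tilt_db * math.log2(h) / 20.0)
                harm += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
            harm /= max(np.sqrt(np.mean(harm ** 2)), 1e-12)
        else:
            harm = np.zeros(n)
        if nf > 0.0:
            noise = rng.standard_normal(n)
            noise /= np.sqrt(np.mean(noise ** 2))
        else:
            noise = np.zeros(n)
        x = np.sqrt(1.0 - nf) * harm + np.sqrt(nf) * noise
        nr = min(int(ramp_s * sample_rate), n // 2)
        if nr > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            x[:nr] *= ramp
            x[-nr:] *= ramp[::-1]
        pieces.append(x)
        if i < silence_durations.size:
            pieces.append(np.zeros(int(round(silence_durations[i] * sample_rate))))
    return np.concatenate(pieces)


def _draw_bout_params(params: SynthesisParams, rng):
    """Draw concrete per-stimulus synthesis values from a context's preset.

    Beyond the context means, each stimulus gets independent scatter in
    pitch-modulation depth (drawn in absolute Hz over a wide log-range, so
    pitch variability is not simply proportional to pitch), in per-call
    noise fraction (a caller-level shift plus within-bout heterogeneity)
    and in per-call pitch. Real call corpora show exactly this kind of
    within- and between-stimulus variation, and without it the f0 and HNR
    summary statistics would be near-deterministic functions of each other.
    """
    n_calls = int(rng.integers(params.n_calls_range[0], params.n_calls_range[1] + 1))
    durs = rng.uniform(*params.call_dur_range, size=n_calls)
    sils = rng.uniform(*params.silence_range, size=max(n_calls - 1, 0))
    f0 = max(float(rng.normal(params.f0_base_mean, params.f0_base_sd)),
             0.4 * params.f0_base_mean)
    if params.f0_mod_depth > 0:
        mod_hz = 10.0 ** rng.uniform(math.log10(3.0), math.log10(160.0))
        mod_depth = (min(mod_hz / f0, 0.3) * params.f0_mod_depth / 0.1)
    else:
        mod_depth = 0.0
    if params.noise_fraction > 0:
        nf_stim = float(np.clip(rng.normal(params.noise_fraction, 0.10),
                                0.02, 0.85))
        spread = rng.uniform(0.0, 0.25)
        nf_calls = np.clip(nf_stim + rng.uniform(-spread, spread, n_calls),
                           0.02, 0.9)
        # bouts often mix call qualities: occasional near-tonal calls make
        # the peak harmonicity vary independently of the bout average
        clear = rng.random(n_calls) < 0.35
        nf_calls[clear] *= rng.uniform(0.05, 0.4, int(clear.sum()))
    else:
        nf_calls = np.zeros(n_calls)
    f0_scale = rng.normal(1.0, 0.04, n_calls).clip(0.85, 1.15)
    tilt = float(rng.normal(params.spectral_tilt_db, 2.5))
    return f0, durs, sils, mod_depth, nf_calls, f0_scale, tilt


# ---------------------------------------------------------------------------
# corpus generation

def generate_corpus(config: CorpusConfig, seed: int, out_dir) -> pd.DataFrame:
    """Generate the full stimulus corpus under ``out_dir``.

    Writes one peak-normalized 16-bit mono PCM WAV per stimulus plus a
    ``stimuli.csv`` metadata table and returns that table. ``wav_path`` is
    stored relative to ``out_dir`` so that identical seeds yield
    byte-identical metadata regardless of where the corpus lives.
    """
    from pathlib import Path

    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "wavs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    caller_offset = 0
    stim_idx = 0
    for prof in config.profiles:
        pool = [f"ch{caller_offset + j + 1:02d}" for j in range(prof.caller_pool)]
        caller_offset += prof.caller_pool
        # every caller in the pool contributes at least one stimulus
        callers = pool + list(rng.choice(pool, size=prof.n_stimuli - len(pool)))
        rng.shuffle(callers)
        for caller in callers:
            stim_idx += 1
            sid = f"s{stim_idx:03d}"
            (f0, durs, sils, mod_depth, nf_calls, f0_scale,
             tilt) = _draw_bout_params(prof.synthesis, rng)
            wave = synthesize_call_bout(
                f0, durs, sils,
                noise_fraction=nf_calls,
                spectral_tilt_db=tilt,
                f0_mod_depth=mod_depth,
                f0_call_scale=f0_scale,
                sample_rate=config.sample_rate,
                rng=rng,
            )
            peak = np.max(np.abs(wave))
            if peak > 0:
                wave = wave * (config.peak_target / peak)
            pcm = np.round(wave * 32767.0).astype(np.int16)
            rel = f"wavs/{sid}.wav"
            wavfile.write(out_dir / rel, config.sample_rate, pcm)
            rows.append({
                "stimulus_id": sid,
                "caller_id": caller,
                "context_id": prof.context_id,
                "context_label": prof.label,
                "arousal": prof.arousal_class,
                "valence": prof.valence_class,
                "wav_path": rel,
                "duration_s": round(len(pcm) / config.sample_rate, 6),
                "f0_base_hz": round(f0, 3),
                "n_calls_true": len(durs),
                "noise_fraction": round(float(np.mean(nf_calls)), 4),
            })
    stimuli = pd.DataFrame(rows)
    stimuli.to_csv(out_dir / "stimuli.csv", index=False)
    return stimuli


# ---------------------------------------------------------------------------
# listener models

@dataclass(frozen=True)
class ListenerModel:
    """Generative model of one homogeneous listener population.

    ``context_weights`` are per-context log-odds of the true context's
    response option relative to each of the 9 alternatives in the 10-way
    task; ``exp2_sensitivity`` is the log-odds boost for a matching trial in
    the yes/no task. ``valence_bias`` shifts the mean of the recoded
    (−2..+2) valence rating, encoding the tendency to judge calls as
    negative. ``lapse_rate`` is the probability of a uniform random
    response; at 1 every behaviour is uniform guessing.
    """

    context_weights: dict = field(default_factory=dict)
    arousal_gain: dict = field(default_factory=lambda: {"high": 1.1, "medium": 0.0, "low": -1.1})
    valence_gain: dict = field(default_factory=lambda: {"positive": 0.7, "negative": -0.7, "none": 0.0})
    valence_bias: float = -0.35
    rating_sd: float = 1.0
    lapse_rate: float = 0.08
    exp2_sensitivity: dict = field(default_factory=dict)
    exp2_bias: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")

    def weight(self, context_id: str) -> float:
        return self.context_weights.get(context_id, 0.0)

    def sensitivity(self, context_id: str) -> float:
        return self.exp2_sensitivity.get(context_id, 0.0)


def default_listener() -> ListenerModel:
    """Qualitative-findings preset: above-chance core-affect judgments, a
    negativity bias, and higher sensitivity for negative than positive
    contexts in the match-to-context task."""
    neg = {p.context_id for p in PAPER_CONTEXTS if p.valence_class == "negative"}
    weights = {p.context_id: (1.2 if p.context_id in neg else 0.7)
               for p in PAPER_CONTEXTS}
    sens = {p.context_id: (1.1 if p.context_id in neg else 0.55)
            for p in PAPER_CONTEXTS}
    return ListenerModel(context_weights=weights, exp2_sensitivity=sens)


def null_listener() -> ListenerModel:
    """Lapse-only listener: every response is uniform guessing."""
    return ListenerModel(lapse_rate=1.0, valence_bias=0.0)


def _p_true_choice(weight: float, k: int = 10) -> float:
    """Softmax probability of the truth-aligned option (others at logit 0)."""
    if np.isinf(weight) and weight > 0:
        return 1.0
    e = np.exp(weight)
    return float(e / (e + (k - 1)))


def _discretize_rating(latent: np.ndarray) -> np.ndarray:
    """Map latent values to 1..5 ratings (recoded scale −2..2 plus 3)."""
    return np.clip(np.rint(latent), -2, 2).astype(int) + 3


def simulate_exp1(stimuli: pd.DataFrame, n_participants: int,
                  listener: ListenerModel, seed: int) -> pd.DataFrame:
    """Simulate the 10-way categorization + rating experiment.

    Each participant hears every stimulus once in an individually
    randomized order and produces a context choice and 5-point arousal and
    valence ratings per trial.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    contexts = list(dict.fromkeys(stimuli["context_id"]))
    k = len(contexts)
    n_stim = len(stimuli)
    sid = stimuli["stimulus_id"].to_numpy()
    true_ctx = stimuli["context_id"].to_numpy()
    p_true = np.array([_p_true_choice(listener.weight(c), k) for c in true_ctx])
    arousal_mu = stimuli["arousal"].map(listener.arousal_gain).to_numpy(float)
    valence_mu = (stimuli["valence"].map(listener.valence_gain).to_numpy(float)
                  + listener.valence_bias)
    ctx_arr = np.array(contexts)
    other = {c: ctx_arr[ctx_arr != c] for c in contexts}

    frames = []
    for p in range(n_participants):
        order = rng.permutation(n_stim)
        lapse = rng.random(n_stim) < listener.lapse_rate
        pick_true = rng.random(n_stim) < p_true[order]
        chosen = np.where(pick_true, true_ctx[order], "")
        for i in np.flatnonzero(~pick_true):
            chosen[i] = rng.choice(other[true_ctx[order[i]]])
        chosen[lapse] = rng.choice(ctx_arr, size=int(lapse.sum()))
        ar = _discretize_rating(arousal_mu[order]
                                + rng.normal(0, listener.rating_sd, n_stim))
        va = _discretize_rating(valence_mu[order]
                                + rng.normal(0, listener.rating_sd, n_stim))
        ar[lapse] = rng.integers(1, 6, int(lapse.sum()))
        va[lapse] = rng.integers(1, 6, int(lapse.sum()))
        frames.append(pd.DataFrame({
            "participant_id": f"p{p + 1:04d}",
            "stimulus_id": sid[order],
            "trial_index": np.arange(1, n_stim + 1),
            "chosen_context": chosen,
            "arousal_rating": ar,
            "valence_rating": va,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_exp2(stimuli: pd.DataFrame, condition_context: str,
                  n_participants: int, listener: ListenerModel,
                  seed: int) -> pd.DataFrame:
    """Simulate the yes/no match-to-context experiment for one condition.

    Per participant, the matching set is a random half (floor) of the
    condition context's stimuli and the non-matching set is three times as
    many stimuli drawn from the other contexts, so matching trials are one
    fourth of the session.
    """
    if condition_context not in set(stimuli["context_id"]):
        raise ValueError(f"unknown context {condition_context!r}")
    in_ctx = stimuli.loc[stimuli["context_id"] == condition_context, "stimulus_id"].to_numpy()
    out_ctx = stimuli.loc[stimuli["context_id"] != condition_context, "stimulus_id"].to_numpy()
    if len(in_ctx) < 2:
        raise ValueError("condition context needs at least 2 stimuli")
    n_match = len(in_ctx) // 2
    n_non = 3 * n_match
    if n_non > len(out_ctx):
        raise ValueError("not enough non-matching stimuli available")
    rng = np.random.default_rng(seed)
    sens = listener.sensitivity(condition_context)
    p_yes_match = ((1 - listener.lapse_rate) * expit(listener.exp2_bias + sens)
                   + listener.lapse_rate * 0.5)
    p_yes_non = ((1 - listener.lapse_rate) * expit(listener.exp2_bias)
                 + listener.lapse_rate * 0.5)

    frames = []
    for p in range(n_participants):
        match = rng.choice(in_ctx, size=n_match, replace=False)
        non = rng.choice(out_ctx, size=n_non, replace=False)
        stim = np.concatenate([match, non])
        is_match = np.concatenate([np.ones(n_match, bool), np.zeros(n_non, bool)])
        order = rng.permutation(len(stim))
        p_yes = np.where(is_match[order], p_yes_match, p_yes_non)
        frames.append(pd.DataFrame({
            "participant_id": f"p{p + 1:04d}",
            "condition_context": condition_context,
            "stimulus_id": stim[order],
            "is_match": is_match[order],
            "response_yes": rng.random(len(stim)) < p_yes,
            "trial_index": np.arange(1, len(stim) + 1),
        }))
    return pd.concat(frames, ignore_index=True)


def nominal_dprime(listener: ListenerModel, context_id: str) -> float:
    """Closed-form d′ implied by the exp-2 response model for a context."""
    sens = listener.sensitivity(context_id)
    p_hit = ((1 - listener.lapse_rate) * expit(listener.exp2_bias + sens)
             + listener.lapse_rate * 0.5)
    p_fa = ((1 - listener.lapse_rate) * expit(listener.exp2_bias)
            + listener.lapse_rate * 0.5)
    return float(norm.ppf(p_hit) - norm.ppf(p_fa))
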