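"""Acoustic feature extraction for call bouts.

Measures the 15 per-stimulus acoustic parameters the analysis models use:
bout segmentation (number of calls, total called duration), an
autocorrelation f0 track (min/max/mean/sd over voiced frames, percentage of
voiced frames), harmonics-to-noise ratio statistics (mean/max/sd),
cycle-to-cycle perturbation (jitter and shimmer, local, in percent) and
spectral measures (spectral centre of gravity, time of the maximum peak
frequency and its relative position within the bout).

All features are computed per bout, deterministically for a fixed
configuration, and are invariant to overall gain (every measure is either
normalized or relative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import find_peaks


@dataclass(frozen=True)
class AcousticConfig:
    """Analysis settings.

    The f0 search range 70–1800 Hz spans the chimpanzee call range (grunts
    through screams). The voicing decision uses the height of the
    normalized-autocorrelation peak, as in standard cross-correlation pitch
    trackers.
    """

    frame_s: float = 0.04          # f0/HNR analysis frame
    hop_s: float = 0.01
    f0_floor: float = 70.0         # Hz
    f0_ceiling: float = 1800.0     # Hz
    voicing_threshold: float = 0.45
    seg_frame_s: float = 0.01      # non-overlapping RMS frames for segmentation
    seg_threshold_db: float = 25.0  # below bout peak frame RMS
    min_silence_s: float = 0.05
    min_call_s: float = 0.03
    hnr_cap_db: float = 40.0
    octave_candidate_ratio: float = 0.9  # accept shorter-lag peaks this close to the best
    dip_ratio: float = 0.5  # a peak counts only after r dips below this fraction of it

    def __post_init__(self) -> None:
        if self.f0_floor >= self.f0_ceiling:
            raise ValueError("f0 floor must be below the ceiling")


@dataclass(frozen=True)
class CallSegment:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FrameTrack:
    """Per-frame pitch/voicing analysis. f0 and hnr are NaN where unvoiced."""

    frame_times: np.ndarray
    f0: np.ndarray
    voiced_flag: np.ndarray
    hnr: np.ndarray
    in_segment: np.ndarray
    frame_length: float
    hop: float


#: Canonical order of the 15 extracted parameters.
FEATURE_NAMES = (
    "n_calls", "duration", "time_max_peak_freq", "rel_peak_position",
    "percent_voiced", "jitter", "shimmer", "scog",
    "f0_min", "f0_max", "f0_mean", "f0_sd",
    "hnr_mean", "hnr_max", "hnr_sd",
)


@dataclass(frozen=True)
class AcousticFeatures:
    n_calls: float
    duration: float
    time_max_peak_freq: float
    rel_peak_position: float
    percent_voiced: float
    jitter: float
    shimmer: float
    scog: float
    f0_min: float
    f0_max: float
    f0_mean: float
    f0_sd: float
    hnr_mean: float
    hnr_max: float
    hnr_sd: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# segmentation

def segment_calls(waveform, sample_rate: int,
                  config: AcousticConfig = AcousticConfig()) -> list[CallSegment]:
    """Split a bout into call segments by relative RMS energy.

    Active frames are those whose RMS lies within ``seg_threshold_db`` of
    the loudest frame; gaps shorter than ``min_silence_s`` are merged and
    runs shorter than ``min_call_s`` dropped.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    flen = max(int(round(config.seg_frame_s * sample_rate)), 1)
    n_frames = x.size // flen
    if n_frames == 0:
        return []
    rms = np.sqrt(np.mean(x[: n_frames * flen].reshape(n_frames, flen) ** 2, axis=1))
    peak = rms.max()
    if peak <= 0:
        return []
    active = 20 * np.log10(np.maximum(rms, 1e-12)) > 20 * np.log10(peak) - config.seg_threshold_db

    runs = _runs(active)
    # merge runs separated by short gaps
    merged: list[list[int]] = []
    max_gap = int(round(config.min_silence_s / config.seg_frame_s))
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < max_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    min_len = config.min_call_s / config.seg_frame_s
    out = []
    for i0, i1 in merged:
        if i1 - i0 >= min_len:
            out.append(CallSegment(i0 * config.seg_frame_s, i1 * config.seg_frame_s))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


# ---------------------------------------------------------------------------
# pitch tracking

def _frame_matrix(x: np.ndarray, flen: int, hop: int):
    if x.size < flen:
        return np.empty((0, flen)), np.empty(0, dtype=int)
    frames = sliding_window_view(x, flen)[::hop]
    starts = np.arange(0, x.size - flen + 1, hop)
    return np.array(frames, dtype=float), starts


def _norm_autocorr(frames: np.ndarray, lag_min: int, lag_max: int):
    """Normalized autocorrelation r(tau) for each row, tau in [lag_min, lag_max].

    r(tau) = sum x[t] x[t+tau] / sqrt(sum_{t<L-tau} x^2 * sum_{t>=tau} x^2),
    computed with an FFT for the numerator and cumulative sums for the
    denominators.
    """
    F, L = frames.shape
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = 1 << int(math.ceil(math.log2(2 * L)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]
    sq = np.concatenate([np.zeros((F, 1)), np.cumsum(frames ** 2, axis=1)], axis=1)
    taus = np.arange(lag_min - 1, min(lag_max + 2, L))
    e_head = sq[:, L - taus]                   # energy of x[0 : L-tau]
    e_tail = sq[:, [L]] - sq[:, taus]          # energy of x[tau : L]
    denom = np.sqrt(np.maximum(e_head * e_tail, 1e-300))
    r = np.zeros((F, lag_max + 2))
    r[:, taus] = ac[:, taus] / denom
    return r


def _best_lag(r_row: np.ndarray, lag_min: int, lag_max: int,
              candidate_ratio: float, dip_ratio: float = 0.5):
    """Pick the pitch-period lag from one autocorrelation row.

    A local maximum only counts as a period candidate if the
    autocorrelation has first dipped below ``dip_ratio`` times its height —
    at short lags r is still high for any band-limited signal and noise
    puts spurious micro-peaks on that plateau. The strongest candidate sets
    the period hypothesis; if a nearly-as-strong candidate (within
    ``candidate_ratio``) sits at an integer fraction of that lag, the
    shorter lag wins, which suppresses sub-harmonic (octave-down) errors
    without letting noise-displaced neighbours of the true peak bias the
    estimate. Returns (lag, strength) with parabolic interpolation, or
    (nan, 0) if no candidate.
    """
    seg = r_row[lag_min : lag_max + 1]
    if seg.size < 3:
        return np.nan, 0.0
    interior = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
    if interior.size == 0:
        return np.nan, 0.0
    peaks = interior + lag_min
    strengths = r_row[peaks]
    prefix_min = np.minimum.accumulate(seg)[peaks - lag_min]
    ok = prefix_min <= dip_ratio * strengths
    peaks, strengths = peaks[ok], strengths[ok]
    if peaks.size == 0:
        return np.nan, 0.0
    best_i = int(np.argmax(strengths))
    best_lag, best_r = int(peaks[best_i]), float(strengths[best_i])
    choice = best_i
    for k in range(best_lag // lag_min, 1, -1):
        target = best_lag / k
        if target < lag_min:
            continue
        tol = max(0.06 * target, 2.0)
        sel = np.flatnonzero((np.abs(peaks - target) <= tol)
                             & (strengths >= candidate_ratio * best_r))
        if sel.size:
            choice = int(sel[np.argmax(strengths[sel])])
            break
    lag = int(peaks[choice])
    rm, r0, rp = r_row[lag - 1], r_row[lag], r_row[lag + 1]
    denom = rm - 2 * r0 + rp
    delta = 0.5 * (rm - rp) / denom if abs(denom) > 1e-12 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    strength = float(min(r0 - 0.25 * (rm - rp) * delta, 1.0 - 1e-9))
    return lag + delta, strength


def track_f0(waveform, sample_rate: int,
             config: AcousticConfig = AcousticConfig(),
             segments: list[CallSegment] | None = None) -> FrameTrack:
    """Frame-wise f0 and voicing by normalized autocorrelation.

    A frame is voiced iff its autocorrelation peak is at least the voicing
    threshold, the implied f0 lies within [floor, ceiling], and the frame
    centre falls inside a call segment. HNR per voiced frame is
    10*log10(r / (1-r)) at the chosen lag, capped at ``hnr_cap_db``.
    """
    x = np.asarray(waveform, dtype=float)
    if segments is None:
        segments = segment_calls(x, sample_rate, config)
    flen = int(round(config.frame_s * sample_rate))
    hop = max(int(round(config.hop_s * sample_rate)), 1)
    frames, starts = _frame_matrix(x, flen, hop)
    n = frames.shape[0]
    times = (starts + flen / 2) / sample_rate
    f0 = np.full(n, np.nan)
    hnr = np.full(n, np.nan)
    voiced = np.zeros(n, dtype=bool)
    in_seg = np.zeros(n, dtype=bool)
    for s in segments:
        in_seg |= (times >= s.start) & (times <= s.end)
    if n:
        lag_min = max(int(np.floor(sample_rate / config.f0_ceiling)), 2)
        lag_max = min(int(np.ceil(sample_rate / config.f0_floor)), flen - 2)
        r = _norm_autocorr(frames, lag_min, lag_max)
        for i in range(n):
            if not in_seg[i]:
                continue
            lag, strength = _best_lag(r[i], lag_min, lag_max,
                                      config.octave_candidate_ratio,
                                      config.dip_ratio)
            if not np.isfinite(lag) or strength < config.voicing_threshold:
                continue
            freq = sample_rate / lag
            if not config.f0_floor <= freq <= config.f0_ceiling:
                continue
            voiced[i] = True
            f0[i] = freq
            rr = min(max(strength, 1e-9), 1.0 - 1e-9)
            hnr[i] = min(10 * np.log10(rr / (1 - rr)), config.hnr_cap_db)
    if voiced.any():
        # 5-frame running median de-spikes isolated octave errors while
        # leaving slow contours (glides) intact
        raw = f0.copy()
        for i in np.flatnonzero(voiced):
            f0[i] = np.nanmedian(raw[max(i - 2, 0): i + 3])
    return FrameTrack(times, f0, voiced, hnr, in_seg,
                      flen / sample_rate, hop / sample_rate)


def harmonicity(waveform, track: FrameTrack,
                config: AcousticConfig = AcousticConfig()):
    """HNR mean/max/sd in dB over voiced frames (NaNs if none are voiced)."""
    h = track.hnr[track.voiced_flag]
    if h.size == 0:
        return math.nan, math.nan, math.nan
    return float(h.mean()), float(h.max()), float(h.std())


# ---------------------------------------------------------------------------
# perturbation

def perturbation(waveform, sample_rate: int, track: FrameTrack,
                 config: AcousticConfig = AcousticConfig(),
                 expected_f0: float | None = None):
    """Local jitter and shimmer (%) from period marks in voiced spans.

    Period marks are waveform peaks picked at roughly the voiced-span
    period; jitter is the mean absolute difference of consecutive periods
    over the mean period, shimmer the analogue on peak amplitudes. Requires
    at least three consecutive periods; otherwise both are NaN.

    ``expected_f0`` overrides the period prior taken from the f0 track —
    useful for controlled measurements where the nominal pulse rate is
    known (e.g. a strictly alternating period sequence is periodic at half
    the pulse rate, so the track legitimately reports the subharmonic).
    """
    x = np.asarray(waveform, dtype=float)
    dT, T, dA, A = [], [], [], []
    for i0, i1 in _runs(track.voiced_flag):
        if i1 - i0 < 2:
            continue
        med_f0 = expected_f0 if expected_f0 else np.nanmedian(track.f0[i0:i1])
        if not np.isfinite(med_f0) or med_f0 <= 0:
            continue
        t0 = track.frame_times[i0] - track.frame_length / 2
        t1 = track.frame_times[i1 - 1] + track.frame_length / 2
        s0, s1 = int(t0 * sample_rate), min(int(t1 * sample_rate), x.size)
        seg = x[s0:s1]
        period = sample_rate / med_f0
        peaks, _ = find_peaks(seg, distance=max(int(0.7 * period), 1),
                              height=0.2 * np.max(np.abs(seg)))
        if peaks.size < 4:
            continue
        pos = peaks.astype(float)
        amp = seg[peaks].astype(float)
        for j, pk in enumerate(peaks):  # parabolic refinement of each mark
            if 0 < pk < seg.size - 1:
                ym, y0, yp = seg[pk - 1], seg[pk], seg[pk + 1]
                den = ym - 2 * y0 + yp
                if abs(den) > 1e-12:
                    d = 0.5 * (ym - yp) / den
                    if abs(d) <= 0.5:
                        pos[j] = pk + d
                        amp[j] = y0 - 0.25 * (ym - yp) * d
        periods = np.diff(pos) / sample_rate
        ok = (periods > 0.6 * period / sample_rate) & (periods < 1.6 * period / sample_rate)
        for j in range(len(periods) - 1):
            if ok[j] and ok[j + 1]:
                dT.append(abs(periods[j + 1] - periods[j]))
                dA.append(abs(amp[j + 2] - amp[j + 1]))
        T.extend(periods[ok])
        A.extend(np.abs(amp[1:][ok]))
    if len(T) < 3 or not dT:
        return math.nan, math.nan
    jitter = 100.0 * np.mean(dT) / np.mean(T)
    shimmer = 100.0 * np.mean(dA) / np.mean(A)
    return float(jitter), float(shimmer)


# ---------------------------------------------------------------------------
# spectral measures

def spectral_features(waveform, sample_rate: int,
                      segments: list[CallSegment],
                      config: AcousticConfig = AcousticConfig()):
    """Spectral centre of gravity and peak-frequency timing.

    SCoG is the power-weighted mean frequency of the whole-bout spectrum.
    The peak time is the centre of the spectrogram frame holding the global
    maximum magnitude, and its relative position is that time as a fraction
    of the span from first segment start to last segment end.
    """
    if not segments:
        return math.nan, math.nan, math.nan
    x = np.asarray(waveform, dtype=float)
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / sample_rate)
    total = power.sum()
    scog = float((freqs * power).sum() / total) if total > 0 else math.nan

    flen = int(round(config.frame_s * sample_rate))
    hop = max(int(round(config.hop_s * sample_rate)), 1)
    frames, starts = _frame_matrix(x, flen, hop)
    if frames.shape[0] == 0:
        return scog, math.nan, math.nan
    mag = np.abs(np.fft.rfft(frames * np.hanning(flen), axis=1))
    peak_frame = int(np.unravel_index(np.argmax(mag), mag.shape)[0])
    t_peak = float((starts[peak_frame] + flen / 2) / sample_rate)
    span0, span1 = segments[0].start, segments[-1].end
    rel = (t_peak - span0) / (span1 - span0) if span1 > span0 else 0.5
    return scog, t_peak, float(np.clip(rel, 0.0, 1.0))


# ---------------------------------------------------------------------------
# composition

def extract_features_from_waveform(waveform, sample_rate: int,
                                   config: AcousticConfig = AcousticConfig()
                                   ) -> AcousticFeatures:
    x = np.asarray(waveform, dtype=float)
    segments = segment_calls(x, sample_rate, config)
    track = track_f0(x, sample_rate, config, segments)
    scog, t_peak, rel = spectral_features(x, sample_rate, segments, config)
    hnr_mean, hnr_max, hnr_sd = harmonicity(x, track, config)
    jitter, shimmer = perturbation(x, sample_rate, track, config)
    n_in_seg = int(track.in_segment.sum())
    pv = 100.0 * track.voiced_flag.sum() / n_in_seg if n_in_seg else math.nan
    f0v = track.f0[track.voiced_flag]
    return AcousticFeatures(
        n_calls=len(segments),
        duration=float(sum(s.duration for s in segments)),
        time_max_peak_freq=t_peak,
        rel_peak_position=rel,
        percent_voiced=pv,
        jitter=jitter,
        shimmer=shimmer,
        scog=scog,
        f0_min=float(f0v.min()) if f0v.size else math.nan,
        f0_max=float(f0v.max()) if f0v.size else math.nan,
        f0_mean=float(f0v.mean()) if f0v.size else math.nan,
        f0_sd=float(f0v.std()) if f0v.size else math.nan,
        hnr_mean=hnr_mean,
        hnr_max=hnr_max,
        hnr_sd=hnr_sd,
    )


def read_wav(path):
    """Read a PCM WAV as (float waveform in [-1, 1], sample rate)."""
    sr, data = wavfile.read(path)
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), sr


def extract_features(wav_path, config: AcousticConfig = AcousticConfig()
                     ) -> AcousticFeatures:
    """Extract the 15 acoustic parameters from one WAV file."""
    x, sr = read_wav(wav_path)
    return extract_features_from_waveform(x, sr, config)


def extract_features_table(stimuli, base_dir,
                           config: AcousticConfig = AcousticConfig()):
    """Run :func:`extract_features` for every stimulus row.

    ``stimuli`` must carry ``stimulus_id`` and ``wav_path`` (relative to
    ``base_dir``). Returns one row per stimulus with the 15 feature columns.
    """
    import pandas as pd
    from pathlib import Path

    base = Path(base_dir)
    rows = []
    for rec in stimuli.itertuples(index=False):
        feats = extract_features(base / rec.wav_path, config)
        rows.append({"stimulus_id": rec.stimulus_id, **feats.to_dict()})
    return pd.DataFrame(rows)
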