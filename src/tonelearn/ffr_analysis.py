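"""Frequency-following-response (FFR) pitch-encoding pipeline.

The FFR is a scalp potential phase-locked to the fundamental frequency of
an auditory stimulus.  This module implements the standard desk pipeline
for scoring how well a listener's FFR encodes Mandarin tone pitch:

1. zero-phase band-pass filtering (80-1000 Hz, the phase-locking range of
   brainstem neurons);
2. epoch segmentation at a 7 ms neural latency, baseline correction to the
   pre-stimulus noise floor, +/-50 uV artifact rejection, and averaging;
3. autocorrelation pitch tracking with a 40 ms window sliding in 10 ms
   steps (30 ms overlap);
4. the stimulus-to-response Pearson correlation between stimulus and
   response F0 contours (the pitch-encoding quality score);
5. linear mixed models of encoding quality (group x session with subject
   intercepts);
6. hidden-Markov-model decoding of tone category from resampled FFR
   sub-averages, scored as percent confusion, and pre/post confusion
   change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

import statsmodels.formula.api as smf

from .glmm import MixedModelFit
from .types import EpochSet, PitchTrack, Recording

DEFAULT_BAND = (80.0, 1000.0)
DEFAULT_F0_RANGE = (60.0, 400.0)
VOICING_THRESHOLD = 0.3  # normalized autocorrelation peak


# ---------------------------------------------------------------------------
# filtering and epoching
# ---------------------------------------------------------------------------

def bandpass_zero_phase(
    data: np.ndarray | Recording,
    fs: float | None = None,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
) -> np.ndarray | Recording:
    """Zero-phase second-order Butterworth band-pass.

    The second-order design is applied forward and backward (filtfilt), so
    the net group delay is zero and the effective magnitude response is
    fourth-order.
    """
    if isinstance(data, Recording):
        return Recording(bandpass_zero_phase(data.data, data.fs, lo, hi), data.fs)
    if fs is None:
        raise ValueError("fs required for array input")
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError(f"hi = {hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(data, dtype=float))


def segment_ffr_epochs(
    recording: Recording,
    onsets: np.ndarray,
    stimulus_duration: float,
    latency: float = 0.007,
    baseline: tuple[float, float] = (-0.040, 0.0),
    reject_uv: float = 50.0,
    stimulus=None,
) -> EpochSet:
    """Cut, baseline-correct and artifact-reject single-trial FFR epochs.

    Each epoch spans ``[onset + latency, onset + latency + duration)``;
    the mean of the pre-onset baseline window (relative to onset, default
    -40..0 ms) is subtracted, and corrected epochs with any sample beyond
    ``+/- reject_uv`` are dropped and counted.  Epochs whose windows fall
    outside the recording are dropped with a warning.
    """
    fs = recording.fs
    n_epoch = int(round(stimulus_duration * fs))
    kept, n_rejected = [], 0
    for onset in np.asarray(onsets, dtype=float):
        start = int(round((onset + latency) * fs))
        b0 = int(round((onset + baseline[0]) * fs))
        b1 = int(round((onset + baseline[1]) * fs))
        if b0 < 0 or start + n_epoch > recording.n_samples:
            warnings.warn(
                f"epoch at onset {onset:.4f} s extends past the recording; dropped",
                stacklevel=2,
            )
            continue
        epoch = recording.data[start : start + n_epoch].copy()
        epoch -= recording.data[b0:b1].mean() if b1 > b0 else 0.0
        if np.any(np.abs(epoch) > reject_uv):
            n_rejected += 1
            continue
        kept.append(epoch)
    epochs = np.asarray(kept) if kept else np.empty((0, n_epoch))
    return EpochSet(
        fs=fs,
        epochs=epochs,
        window=(latency, latency + stimulus_duration),
        latency_applied=latency,
        n_rejected=n_rejected,
        stimulus=stimulus,
    )


def average_epochs(epoch_set: EpochSet) -> tuple[np.ndarray, int]:
    """Pointwise mean of the surviving epochs; returns (waveform, n)."""
    if epoch_set.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    return epoch_set.epochs.mean(axis=0), epoch_set.n_epochs


# ---------------------------------------------------------------------------
# autocorrelation pitch tracking
# ---------------------------------------------------------------------------

def n_frames(n_samples: int, frame_n: int, hop_n: int) -> int:
    """Closed-form frame count: 1 + floor((L - frame) / hop)."""
    if n_samples < frame_n:
        raise ValueError("waveform shorter than one analysis frame")
    return 1 + (n_samples - frame_n) // hop_n


def track_pitch_autocorr(
    waveform: np.ndarray,
    fs: float,
    frame: float = 0.040,
    overlap: float = 0.030,
    f0_range: tuple[float, float] = DEFAULT_F0_RANGE,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> PitchTrack:
    """Short-time autocorrelation F0 tracking.

    Frames of ``frame`` seconds slide in steps of ``frame - overlap``
    (default 10 ms).  Per frame the unbiased autocorrelation is evaluated
    over lags inside ``f0_range``; the peak lag, refined by parabolic
    interpolation, gives F0 = fs / lag.  Frames whose normalized peak falls
    below ``voicing_threshold`` are marked unvoiced (NaN).  The tracker is
    invariant to positive amplitude scaling.
    """
    waveform = np.asarray(waveform, dtype=float)
    hop = frame - overlap
    if hop <= 0:
        raise ValueError("overlap must be smaller than the frame length")
    frame_n = int(round(frame * fs))
    hop_n = max(int(round(hop * fs)), 1)
    lag_min = int(np.floor(fs / f0_range[1]))
    lag_max = int(np.ceil(fs / f0_range[0]))
    lag_max = min(lag_max, frame_n - 2)
    if lag_min < 1 or lag_min >= lag_max:
        raise ValueError("f0_range empty after clipping to the frame length")
    count = n_frames(waveform.size, frame_n, hop_n)
    times = np.empty(count)
    f0 = np.full(count, np.nan)
    for i in range(count):
        seg = waveform[i * hop_n : i * hop_n + frame_n]
        seg = seg - seg.mean()
        times[i] = (i * hop_n + frame_n / 2) / fs
        denom = np.dot(seg, seg) / frame_n
        if denom <= 0:
            continue
        # unbiased autocorrelation over the candidate lag range
        full = np.correlate(seg, seg, mode="full")[frame_n - 1 :]
        lags = np.arange(frame_n)
        with np.errstate(invalid="ignore", divide="ignore"):
            acf = full / (frame_n - lags)
        acf /= denom
        window = acf[lag_min : lag_max + 1]
        # prefer the smallest-lag peak within 10% of the window maximum to
        # avoid octave-down errors (lag 2T scores as well as lag T for a
        # periodic signal)
        interior = (window[1:-1] >= window[:-2]) & (window[1:-1] >= window[2:])
        peak_lags = np.flatnonzero(interior) + 1 + lag_min
        if peak_lags.size:
            best = acf[peak_lags].max()
            k = int(peak_lags[acf[peak_lags] >= 0.9 * best][0])
        else:
            k = int(np.argmax(window)) + lag_min
        # voicing: Pearson correlation between the frame and its lag-k copy
        # (bounded by 1, unlike the unbiased ACF which inflates long lags)
        a, b = seg[: frame_n - k], seg[k:]
        sa, sb = a.std(), b.std()
        rho = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)) if sa > 0 and sb > 0 else 0.0
        if rho < voicing_threshold:
            continue
        # parabolic interpolation around the peak lag
        if 1 <= k < frame_n - 1:
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            denom_p = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom_p if abs(denom_p) > 1e-12 else 0.0
            delta = np.clip(delta, -0.5, 0.5)
        else:
            delta = 0.0
        f0[i] = fs / (k + delta)
    return PitchTrack(times=times, f0=f0, frame_length=frame, hop=hop)


def stimulus_response_r(
    stim_track: PitchTrack, resp_track: PitchTrack
) -> tuple[float, int]:
    """Pearson correlation between stimulus and response pitch contours.

    Both contours are interpolated onto a common frame grid spanning their
    shared voiced support (the response grid restricted to the overlap);
    the correlation runs over frames voiced in both.  Fewer than 3 common
    voiced frames yields ``(nan, n)``.
    """
    grid = resp_track.times
    lo = max(stim_track.times.min(), resp_track.times.min())
    hi = min(stim_track.times.max(), resp_track.times.max())
    grid = grid[(grid >= lo) & (grid <= hi)]
    a = stim_track.interpolate_at(grid)
    b = resp_track.interpolate_at(grid)
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n < 3:
        return float("nan"), n
    if np.std(a[mask]) == 0 or np.std(b[mask]) == 0:
        return float("nan"), n
    r, _ = stats.pearsonr(a[mask], b[mask])
    return float(r), n


# ---------------------------------------------------------------------------
# encoding-quality mixed model
# ---------------------------------------------------------------------------

def fit_encoding_lmm(
    scores: pd.DataFrame,
    reference_levels: dict | None = None,
) -> MixedModelFit:
    """Linear mixed model of encoding quality: r ~ group*session + (1|subject).

    ``scores`` needs columns ``participant, group, session, r`` for a single
    tone (fit one model per tone, as the analysis design prescribes); both
    sessions ('pre', 'post') must be present.
    """
    if "tone" in scores.columns and scores["tone"].nunique() > 1:
        raise ValueError("fit one model per tone: filter the scores table first")
    sessions = set(scores["session"].unique())
    if not {"pre", "post"} <= sessions:
        raise ValueError("both 'pre' and 'post' sessions are required")
    refs = {"group": "Control", "session": "pre"} | dict(reference_levels or {})
    formula = (
        f"r ~ C(group, Treatment('{refs['group']}'))"
        f" * C(session, Treatment('{refs['session']}'))"
    )
    data = scores.reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant"])
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    rename = {
        name: name.replace(f"C(group, Treatment('{refs['group']}'))", "group").replace(
            f"C(session, Treatment('{refs['session']}'))", "session"
        ).replace("[T.", "[")
        for name in fit.fe_params.index
    }
    params = fit.fe_params.rename(rename)
    bse = fit.bse_fe.rename(rename)
    z = params / bse
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)
    diagnostics = [] if fit.converged else ["LMM did not converge"]
    return MixedModelFit(
        formula="r ~ group*session + (1|subject)",
        params=params,
        bse=bse,
        z=z,
        p=p,
        converged=bool(fit.converged),
        vc={
            "participant": float(np.asarray(fit.cov_re)[0, 0]),
            "residual": float(fit.scale),
        },
        reference_levels=refs,
        diagnostics=diagnostics,
        method="reml-lmm",
    )


def flag_low_averaging_n(scores: pd.DataFrame, sd_mult: float = 5.0) -> pd.Series:
    """Flag averaged responses whose trial count is far below the cohort mean.

    Returns a boolean Series aligned with ``scores`` marking rows where
    ``n_averaged`` falls more than ``sd_mult`` standard deviations below
    the mean of the *other* rows (leave-one-out, so a single extreme
    record cannot mask itself); exclusion is left to the caller.
    """
    n = scores["n_averaged"].astype(float).to_numpy()
    total, total_sq, k = n.sum(), (n**2).sum(), n.size
    flags = np.zeros(k, dtype=bool)
    if k < 3:
        return pd.Series(flags, index=scores.index)
    for i in range(k):
        mu = (total - n[i]) / (k - 1)
        var = max(((total_sq - n[i] ** 2) - (k - 1) * mu**2) / (k - 2), 0.0)
        flags[i] = n[i] < mu - sd_mult * np.sqrt(var)
    return pd.Series(flags, index=scores.index)


# ---------------------------------------------------------------------------
# HMM tone decoding
# ---------------------------------------------------------------------------

@dataclass
class ConfusionScore:
    """Percent of FFR sub-averages misclassified by the tone decoder."""

    percent_misclassified: float
    n_test: int
    participant: str | None = None
    session: str | None = None
    per_tone: dict | None = None


def _frame_features(
    waveform: np.ndarray,
    fs: float,
    frame: float,
    overlap: float,
    f0_range: tuple[float, float],
) -> np.ndarray:
    """Frame-wise [F0, log energy] feature sequence for HMM decoding."""
    track = track_pitch_autocorr(
        waveform, fs, frame=frame, overlap=overlap, f0_range=f0_range,
        voicing_threshold=0.0,
    )
    hop_n = max(int(round((frame - overlap) * fs)), 1)
    frame_n = int(round(frame * fs))
    energies = np.array(
        [
            np.log(np.mean(waveform[i * hop_n : i * hop_n + frame_n] ** 2) + 1e-12)
            for i in range(track.f0.size)
        ]
    )
    f0 = track.f0.copy()
    bad = ~np.isfinite(f0)
    if bad.any():
        f0[bad] = np.interp(
            np.flatnonzero(bad), np.flatnonzero(~bad), f0[~bad]
        ) if (~bad).any() else np.mean(f0_range)
    return np.column_stack([f0, energies])


def hmm_decode(
    epochs_by_tone: dict[str, EpochSet],
    train_n: int = 500,
    test_n: int = 500,
    avg_n: int = 200,
    seed: int | None = None,
    n_states: int = 4,
    n_subaverages: int = 50,
    frame: float = 0.040,
    overlap: float = 0.030,
    f0_range: tuple[float, float] = DEFAULT_F0_RANGE,
) -> ConfusionScore:
    """Decode tone category from FFR sub-averages with per-tone HMMs.

    Per tone, the single trials are split into disjoint training
    (``train_n`` trials) and testing (``test_n`` trials) sets; from each
    set ``n_subaverages`` sub-averages are built, each the mean of
    ``avg_n`` trials resampled with replacement within the set.  The
    disjoint split keeps trial-level noise from leaking between training
    and testing, so identically distributed tone sets decode at chance.
    One left-to-right Gaussian-emission HMM per tone is trained on the
    frame-wise [F0, log-energy] sequences of the training sub-averages;
    test sub-averages are assigned to the tone whose model scores higher.
    The confusion score is the percent of test sub-averages misclassified.
    """
    from hmmlearn.hmm import GaussianHMM

    tones = sorted(epochs_by_tone)
    if len(tones) < 2:
        raise ValueError("need epochs for >= 2 tones")
    rng = np.random.default_rng(seed)
    fs = next(iter(epochs_by_tone.values())).fs
    train_feats: dict[str, list[np.ndarray]] = {}
    test_feats: dict[str, list[np.ndarray]] = {}
    for tone in tones:
        eset = epochs_by_tone[tone]
        pool = eset.epochs
        if pool.shape[0] < train_n + test_n:
            raise ValueError(
                f"tone {tone}: {pool.shape[0]} trials < train_n + test_n = "
                f"{train_n + test_n}"
            )
        perm = rng.permutation(pool.shape[0])
        splits = {"train": pool[perm[:train_n]], "test": pool[perm[train_n : train_n + test_n]]}
        for name, part in splits.items():
            feats = []
            for _ in range(n_subaverages):
                idx = rng.integers(0, part.shape[0], size=avg_n)
                feats.append(
                    _frame_features(part[idx].mean(axis=0), fs, frame, overlap, f0_range)
                )
            (train_feats if name == "train" else test_feats)[tone] = feats

    # standardize features with training-set statistics
    all_train = np.vstack([f for fl in train_feats.values() for f in fl])
    mu, sd = all_train.mean(axis=0), all_train.std(axis=0) + 1e-12

    def norm(f: np.ndarray) -> np.ndarray:
        return (f - mu) / sd

    models = {}
    for tone in tones:
        seqs = [norm(f) for f in train_feats[tone]]
        X = np.vstack(seqs)
        lengths = [len(s) for s in seqs]
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=20,
            random_state=int(rng.integers(2**31 - 1)),
            init_params="mc",
            params="stmc",
        )
        # left-to-right topology: zeros are preserved by EM
        start = np.zeros(n_states)
        start[0] = 1.0
        trans = np.zeros((n_states, n_states))
        for i in range(n_states):
            trans[i, i] = 0.6
            if i + 1 < n_states:
                trans[i, i + 1] = 0.4
            else:
                trans[i, i] = 1.0
        model.startprob_ = start
        model.transmat_ = trans
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
        models[tone] = model

    n_wrong = 0
    n_total = 0
    per_tone: dict[str, float] = {}
    for tone in tones:
        wrong = 0
        for f in test_feats[tone]:
            fn = norm(f)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = {t: models[t].score(fn) for t in tones}
            if max(scores, key=scores.get) != tone:
                wrong += 1
        per_tone[tone] = 100.0 * wrong / len(test_feats[tone])
        n_wrong += wrong
        n_total += len(test_feats[tone])
    return ConfusionScore(
        percent_misclassified=100.0 * n_wrong / n_total,
        n_test=n_total,
        per_tone=per_tone,
    )


def confusion_change(pre: ConfusionScore, post: ConfusionScore) -> float:
    """Post-minus-pre confusion change in percentage points."""
    if pre.participant != post.participant:
        raise ValueError("confusion change requires the same participant")
    return post.percent_misclassified - pre.percent_misclassified
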