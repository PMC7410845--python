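"""Sub-threshold vagal evoked potential (VEP) pipeline.

tVNS pulses leave large biphasic square-wave artifacts in the EEG.  The
pipeline locates each pulse by template cross-correlation, excises the
artifact samples and reconstructs the gaps by autoregressive extrapolation
from the surrounding context (so band-pass filtering does not ring), then
epochs the signal around each pulse: the evoked response window (0-15 ms
after pulse offset) is baseline-corrected against the pre-onset window
(-15-0 ms), +/-35 uV epochs are rejected, and survivors are averaged.
Three short-latency components are estimated from the average - N1 (~2 ms),
P1 (~6 ms) and N2 (~11 ms after pulse offset) - and compared against the
baseline response, against stimulation intensity (linear correlation and
the low/intermediate/high inverted-U binning), and against behavioral
learning improvement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .behavior_stats import two_sample_t
from .types import Recording, VepAverage

#: Default N1/P1/N2 search windows (s after pulse offset), bracketing the
#: nominal 2/6/11 ms peak latencies.
PEAK_WINDOWS = {"N1": (0.0, 0.004), "P1": (0.004, 0.009), "N2": (0.009, 0.015)}

#: Stimulation-intensity bins (mA, half-open (lo, hi]) for the inverted-U summary.
INTENSITY_BINS = {"low": (0.2, 1.0), "intermediate": (1.0, 2.0), "high": (2.0, 3.0)}


# ---------------------------------------------------------------------------
# pulse-marker detection
# ---------------------------------------------------------------------------

def detect_pulse_markers(
    recording: Recording,
    template: np.ndarray,
    threshold_frac: float = 0.6,
    refractory_s: float = 0.8 * 0.040,
    pad_s: float = 0.0005,
) -> pd.DataFrame:
    """Locate pulse artifacts by normalized template cross-correlation.

    The template is padded with ``pad_s`` of zeros on each side so a match
    requires both the pulse shape and locally flat surroundings; the
    window-normalized correlation is bounded by 1 (the perfect-match
    score), and local maxima at or above ``threshold_frac`` of it -
    separated by at least ``refractory_s`` (default 80% of the nominal
    40 ms inter-pulse interval at 25 Hz) - are returned as onsets.
    Amplitude scaling of the artifact does not move the markers.

    Returns a DataFrame with 0-based sample columns ``onset, offset,
    score``; an empty frame (no peaks above threshold) is not an error.
    """
    template = np.asarray(template, dtype=float)
    if template.size >= recording.n_samples:
        raise ValueError("template must be shorter than the recording")
    fs = recording.fs
    pad_n = int(round(pad_s * fs))
    padded = np.concatenate([np.zeros(pad_n), template, np.zeros(pad_n)])
    t_z = padded - padded.mean()
    t_norm = np.linalg.norm(t_z)
    if t_norm == 0:
        raise ValueError("template is constant")
    t_z /= t_norm
    x = recording.data
    m = padded.size
    num = sps.correlate(x, t_z, mode="valid")
    ones = np.ones(m)
    s1 = sps.correlate(x, ones, mode="valid")
    s2 = sps.correlate(x * x, ones, mode="valid")
    var = np.clip(s2 - s1 * s1 / m, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(var > 0, num / np.sqrt(var), 0.0)
    distance = max(int(round(refractory_s * fs)), 1)
    peaks, props = sps.find_peaks(ncc, height=threshold_frac, distance=distance)
    onsets = peaks + pad_n
    offsets = onsets + template.size
    return pd.DataFrame(
        {"onset": onsets, "offset": offsets, "score": props["peak_heights"]}
    )


# ---------------------------------------------------------------------------
# artifact excision and AR gap reconstruction
# ---------------------------------------------------------------------------

def _merge_gaps(gaps: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(gaps):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(g) for g in merged]


def _ar_predict(context: np.ndarray, order: int, n_out: int) -> np.ndarray:
    """Least-squares AR fit on ``context``, then forward prediction."""
    order = min(order, context.size - 1)
    if order < 1:
        return np.full(n_out, context[-1] if context.size else 0.0)
    rows = context.size - order
    M = np.empty((rows, order))
    for k in range(order):
        M[:, k] = context[order - 1 - k : context.size - 1 - k]
    target = context[order:]
    coef, *_ = np.linalg.lstsq(M, target, rcond=None)
    hist = list(context[-order:][::-1])  # most recent first
    out = np.empty(n_out)
    for i in range(n_out):
        val = float(np.dot(coef, hist))
        out[i] = val
        hist.insert(0, val)
        hist.pop()
    return out


def excise_and_fill(
    recording: Recording,
    markers: pd.DataFrame,
    pad: float = 0.002,
    ar_order: float | None = None,
) -> Recording:
    """Replace pulse-artifact samples by autoregressive interpolation.

    Samples in each ``[onset, offset)`` gap are reconstructed from AR
    models fitted on the context adjacent to the gap (at least the 2 ms
    pads on each side): a forward prediction from the left context and a
    backward prediction from the right context are crossfaded linearly
    across the gap.  Samples outside the gaps are returned bit-identical.
    Overlapping gaps are merged; a gap at a recording edge falls back to
    one-sided extrapolation with a warning.

    ``ar_order`` defaults to the number of samples in 4 ms.
    """
    out = recording.copy()
    if len(markers) == 0:
        return out
    fs = recording.fs
    order = int(round(0.004 * fs)) if ar_order is None else int(ar_order)
    pad_n = max(int(round(pad * fs)), 1)
    ctx_n = max(3 * order, pad_n)
    gaps = _merge_gaps(
        [(int(a), int(b)) for a, b in zip(markers["onset"], markers["offset"])]
    )
    for a, b in gaps:
        n_gap = b - a
        if n_gap <= 0:
            continue
        left = recording.data[max(a - ctx_n, 0) : a]
        right = recording.data[b : b + ctx_n]
        have_left = left.size > order
        have_right = right.size > order
        if not have_left and not have_right:
            warnings.warn("gap has no usable context; left unchanged", stacklevel=2)
            continue
        if have_left:
            fwd = _ar_predict(left, order, n_gap)
        if have_right:
            bwd = _ar_predict(right[::-1], order, n_gap)[::-1]
        if have_left and have_right:
            w = np.linspace(0.0, 1.0, n_gap + 2)[1:-1]
            fill = (1.0 - w) * fwd + w * bwd
        elif have_left:
            warnings.warn("gap at recording edge: one-sided extrapolation", stacklevel=2)
            fill = fwd
        else:
            warnings.warn("gap at recording edge: one-sided extrapolation", stacklevel=2)
            fill = bwd
        out.data[a:b] = fill
    return out


# ---------------------------------------------------------------------------
# epoching and peak estimation
# ---------------------------------------------------------------------------

def extract_vep_epochs(
    recording: Recording,
    markers: pd.DataFrame,
    response: tuple[float, float] = (0.0, 0.015),
    baseline: tuple[float, float] = (-0.015, 0.0),
    reject_uv: float = 35.0,
) -> tuple[np.ndarray, VepAverage]:
    """Epoch the (filtered, artifact-excised) EEG around each pulse.

    The response window is taken relative to the pulse offset and the
    baseline window relative to the pulse onset; each response epoch has
    its own baseline mean subtracted, epochs exceeding ``+/- reject_uv``
    are rejected, and survivors are averaged into a :class:`VepAverage`.
    """
    fs = recording.fs
    r0 = int(round(response[0] * fs))
    r1 = int(round(response[1] * fs))
    b0 = int(round(baseline[0] * fs))
    b1 = int(round(baseline[1] * fs))
    kept, base_kept = [], []
    n_rejected = 0
    for onset, offset in zip(markers["onset"].astype(int), markers["offset"].astype(int)):
        rs, re = offset + r0, offset + r1
        bs, be = onset + b0, onset + b1
        if bs < 0 or re > recording.n_samples:
            warnings.warn("pulse epoch outside recording; dropped", stacklevel=2)
            continue
        base = recording.data[bs:be]
        epoch = recording.data[rs:re] - base.mean()
        if np.any(np.abs(epoch) > reject_uv):
            n_rejected += 1
            continue
        kept.append(epoch)
        base_kept.append(base - base.mean())
    if not kept:
        raise ValueError("no VEP epochs survived rejection")
    epochs = np.asarray(kept)
    avg = VepAverage(
        fs=fs,
        waveform=epochs.mean(axis=0),
        baseline_waveform=np.asarray(base_kept).mean(axis=0),
        n_epochs=len(kept),
        response_window=response,
        baseline_window=baseline,
    )
    avg.peaks = find_vep_peaks(avg)
    return epochs, avg


def find_vep_peaks(
    avg: VepAverage,
    windows: dict[str, tuple[float, float]] | None = None,
    waveform: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Locate N1/P1/N2 as windowed extrema of the averaged response.

    N-components are the most negative samples of their windows, P1 the
    most positive; returned as ``{name: (latency_s, magnitude_uV)}``.
    An extremum sitting on a window edge (monotone waveform) or an
    all-zero waveform sets ``avg.low_confidence``.
    """
    windows = windows or PEAK_WINDOWS
    wave = avg.waveform if waveform is None else waveform
    times = avg.response_window[0] + np.arange(wave.size) / avg.fs
    peaks: dict[str, tuple[float, float]] = {}
    low_conf = not np.any(wave)
    for name, (lo, hi) in windows.items():
        mask = (times >= lo) & (times < hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            peaks[name] = (np.nan, np.nan)
            low_conf = True
            continue
        seg = wave[idx]
        k = int(np.argmax(seg)) if name.startswith("P") else int(np.argmin(seg))
        if k in (0, idx.size - 1):
            low_conf = True
        peaks[name] = (float(times[idx[k]]), float(seg[k]))
    avg.low_confidence = low_conf
    return peaks


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def test_peaks_vs_baseline(
    peak_magnitudes: pd.DataFrame,
    baseline_magnitudes: pd.DataFrame,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-component t-test of evoked peaks against baseline magnitudes.

    Both frames carry one row per participant and one column per component
    (N1/P1/N2).  The default is a two-sample test; ``paired=True`` runs the
    paired variant on matched participants.
    """
    if len(peak_magnitudes) < 2 or len(baseline_magnitudes) < 2:
        raise ValueError("need >= 2 participants")
    rows = []
    for comp in peak_magnitudes.columns:
        a = peak_magnitudes[comp].dropna()
        b = baseline_magnitudes[comp].dropna()
        if paired:
            common = a.index.intersection(b.index)
            t, p = stats.ttest_rel(a.loc[common], b.loc[common])
            df = len(common) - 1
            rows.append((comp, float(t), float(p), df))
        else:
            t, p, df = two_sample_t(a.to_numpy(), b.to_numpy())
            rows.append((comp, t, p, df))
    return pd.DataFrame(rows, columns=["component", "t", "p", "df"])


def intensity_magnitude_analysis(
    thresholds: pd.Series,
    peaks: pd.DataFrame,
) -> dict:
    """Relate stimulation intensity to evoked-peak magnitude.

    Returns per-component Pearson correlations over matched participants
    and per-bin mean magnitudes over the low (0.2, 1], intermediate (1, 2]
    and high (2, 3] mA intensity ranges (half-open on the left, so 1.0 mA
    falls in the low bin).  Empty bins are reported as NaN.
    """
    common = thresholds.index.intersection(peaks.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched participants")
    x = thresholds.loc[common].astype(float)
    corr_rows, bin_rows = [], []
    for comp in peaks.columns:
        y = peaks.loc[common, comp].astype(float)
        mask = y.notna()
        if mask.sum() >= 3 and y[mask].std() > 0 and x[mask].std() > 0:
            r, p = stats.pearsonr(x[mask], y[mask])
        else:
            r, p = np.nan, np.nan
        corr_rows.append((comp, float(r), float(p), int(mask.sum())))
    for bin_name, (lo, hi) in INTENSITY_BINS.items():
        sel = ((x > lo) & (x <= hi)).to_numpy()
        means = {
            comp: (float(peaks.loc[common[sel], comp].mean()) if sel.any() else np.nan)
            for comp in peaks.columns
        }
        bin_rows.append({"bin": bin_name, "lo_mA": lo, "hi_mA": hi, "n": int(sel.sum()), **means})
    return {
        "correlations": pd.DataFrame(corr_rows, columns=["component", "r", "p", "n"]),
        "binned_means": pd.DataFrame(bin_rows),
    }


def peak_learning_correlation(
    peaks: pd.DataFrame,
    improvement: pd.Series,
) -> pd.DataFrame:
    """Pearson correlation of each component's magnitude with learning gain.

    ``improvement`` is the per-participant percent accuracy improvement.
    A constant improvement vector makes r undefined (reported as NaN).
    """
    common = peaks.index.intersection(improvement.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched participants")
    y = improvement.loc[common].astype(float)
    rows = []
    for comp in peaks.columns:
        a = peaks.loc[common, comp].astype(float)
        mask = a.notna() & y.notna()
        if mask.sum() < 3 or a[mask].std() == 0 or y[mask].std() == 0:
            rows.append((comp, np.nan, np.nan, int(mask.sum())))
            continue
        r, p = stats.pearsonr(a[mask], y[mask])
        rows.append((comp, float(r), float(p), int(mask.sum())))
    return pd.DataFrame(rows, columns=["component", "r", "p", "n"])
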