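"""Shared domain containers for the tone-learning pipeline.

The pipeline passes around a small set of typed objects: pitch contours
(:class:`PitchTrack`), stimulus descriptions (:class:`StimulusSpec`),
continuous recordings (:class:`Recording`) and time-locked epoch sets
(:class:`EpochSet`).  Behavioral trial tables are plain :class:`pandas.DataFrame`
objects with a documented column dictionary (see :mod:`tonelearn.behavior_stats`).

Conventions used throughout the package: time is in seconds, amplitudes in
microvolts, sample indices are 0-based, and epoch windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TONES = ("T1", "T2", "T3", "T4")

#: Tone categories that English learners find perceptually salient (higher /
#: lower pitch height) versus the harder pitch-direction contrasts.
EASY_TONES = frozenset({"T1", "T3"})
HARD_TONES = frozenset({"T2", "T4"})


@dataclass(frozen=True)
class PitchTrack:
    """A fundamental-frequency contour sampled at frame centers.

    Parameters
    ----------
    times:
        Frame-center times in seconds, strictly increasing.
    f0:
        F0 in Hz per frame; ``nan`` marks unvoiced frames.
    frame_length, hop:
        Analysis frame length and hop in seconds (0 for analytically
        defined contours).
    """

    times: np.ndarray
    f0: np.ndarray
    frame_length: float = 0.0
    hop: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0", f0)
        if times.shape != f0.shape:
            raise ValueError("times and f0 must have the same shape")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("PitchTrack times must be strictly increasing")
        voiced = f0[np.isfinite(f0)]
        if voiced.size and np.any(voiced <= 0):
            raise ValueError("voiced F0 values must be positive")

    @property
    def voiced(self) -> np.ndarray:
        """Boolean mask of voiced frames."""
        return np.isfinite(self.f0)

    def interpolate_at(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolate the voiced contour at arbitrary times.

        Times outside the voiced support return ``nan``.
        """
        times = np.asarray(times, dtype=float)
        mask = self.voiced
        if mask.sum() < 2:
            out = np.full(times.shape, np.nan)
            if mask.sum() == 1:
                out[np.isclose(times, self.times[mask][0])] = self.f0[mask][0]
            return out
        t, f = self.times[mask], self.f0[mask]
        out = np.interp(times, t, f, left=np.nan, right=np.nan)
        return out


@dataclass(frozen=True)
class StimulusSpec:
    """One training stimulus: a syllable/talker/tone triple with its F0 contour."""

    syllable: str
    talker: str
    tone: str
    duration: float
    f0: PitchTrack

    def __post_init__(self) -> None:
        if self.tone not in TONES:
            raise ValueError(f"unknown tone category {self.tone!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.f0.times.size and (
            self.f0.times[0] < 0 or self.f0.times[-1] > self.duration + 1e-12
        ):
            raise ValueError("f0 contour must lie within [0, duration]")

    @property
    def label(self) -> str:
        return f"{self.syllable}_{self.talker}_{self.tone}"


@dataclass
class Recording:
    """A continuous single-channel recording in microvolts."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Recording holds a single channel (1-D array)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs)


@dataclass
class EpochSet:
    """Fixed-length time-locked EEG segments with rejection bookkeeping."""

    fs: float
    epochs: np.ndarray  # (n_epochs, n_samples)
    window: tuple[float, float]  # seconds relative to stimulus onset
    latency_applied: float = 0.0
    n_rejected: int = 0
    stimulus: StimulusSpec | None = None

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_presented(self) -> int:
        return self.n_epochs + self.n_rejected

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to stimulus onset (half-open window)."""
        n = self.epochs.shape[1]
        return self.window[0] + np.arange(n) / self.fs


@dataclass
class VepAverage:
    """Averaged pulse-locked response with N1/P1/N2 peak estimates.

    ``waveform`` spans the response window after pulse offset;
    ``baseline_waveform`` spans the pre-onset baseline window.  Peaks are
    ``{"N1"|"P1"|"N2": (latency_s, magnitude_uV)}``; negative components are
    reported with negative magnitudes.
    """

    fs: float
    waveform: np.ndarray
    baseline_waveform: np.ndarray
    n_epochs: int
    response_window: tuple[float, float] = (0.0, 0.015)
    baseline_window: tuple[float, float] = (-0.015, 0.0)
    peaks: dict = field(default_factory=dict)
    low_confidence: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.response_window[0] + np.arange(self.waveform.size) / self.fs
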