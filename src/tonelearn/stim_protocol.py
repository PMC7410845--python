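"""Transcutaneous vagus nerve stimulation (tVNS) protocol simulation.

Covers the three protocol pieces used in the study design: an asymmetric
up/down staircase that finds each participant's perceptual threshold (the
stimulation amplitude is then set 0.2 mA below it), construction of the
biphasic pulse train delivered on stimulated trials, and the condition rule
that decides which trials carry stimulation (tone-paired, feedback-paired,
or none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .types import EASY_TONES, HARD_TONES

#: Hard safety ceiling on stimulation amplitude (mA).
MAX_AMPLITUDE_MA = 3.0


class SafetyLimitError(ValueError):
    """Requested stimulation amplitude exceeds the safety ceiling."""


class StaircaseConvergenceError(RuntimeError):
    """Staircase failed to accumulate the required reversals."""


@dataclass
class StaircaseTrace:
    """Full record of one staircase run."""

    amplitudes: np.ndarray  # mA presented on each trial
    responses: np.ndarray  # True = detected
    reversal_indices: list[int]
    threshold_estimate: float  # mA
    stim_amplitude: float  # mA, threshold - 0.2 floored at 0

    def to_dict(self) -> dict:
        return {
            "amplitudes_mA": self.amplitudes.tolist(),
            "detected": self.responses.astype(int).tolist(),
            "reversal_indices": list(self.reversal_indices),
            "threshold_estimate_mA": self.threshold_estimate,
            "stim_amplitude_mA": self.stim_amplitude,
        }


@dataclass(frozen=True)
class PulseTrain:
    """A train of biphasic square-wave pulses.

    ``onset_re_stimulus`` is the time of the first pulse relative to the
    auditory stimulus onset (negative = before the stimulus).
    """

    n_pulses: int = 15
    pulse_width: float = 150e-6  # seconds per phase
    rate: float = 25.0  # Hz
    amplitude: float = 1.0  # mA
    onset_re_stimulus: float = -0.300  # seconds
    pulse_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude > MAX_AMPLITUDE_MA:
            raise SafetyLimitError(
                f"amplitude {self.amplitude} mA exceeds the {MAX_AMPLITUDE_MA} mA safety limit"
            )
        if self.n_pulses < 1 or self.rate <= 0 or self.pulse_width <= 0:
            raise ValueError("n_pulses, rate and pulse_width must be positive")
        times = self.onset_re_stimulus + np.arange(self.n_pulses) / self.rate
        object.__setattr__(self, "pulse_times", times)

    @property
    def pulse_duration(self) -> float:
        """Duration of one biphasic pulse (both phases)."""
        return 2 * self.pulse_width

    def render_pulse(self, fs: float) -> np.ndarray:
        """Sampled biphasic square pulse: +A then -A, zero net charge.

        Phase widths are rounded to a common sample count so the rendered
        pulse integrates to exactly zero.
        """
        n_phase = max(1, int(round(self.pulse_width * fs)))
        return np.concatenate(
            [np.full(n_phase, self.amplitude), np.full(n_phase, -self.amplitude)]
        )

    def to_dict(self) -> dict:
        return {
            "n_pulses": self.n_pulses,
            "pulse_width_s": self.pulse_width,
            "rate_hz": self.rate,
            "amplitude_mA": self.amplitude,
            "onset_re_stimulus_s": self.onset_re_stimulus,
            "pulse_times_s": self.pulse_times.tolist(),
        }


def build_pulse_train(
    amplitude: float,
    n: int = 15,
    width: float = 150e-6,
    rate: float = 25.0,
    onset_re_stimulus: float = -0.300,
) -> PulseTrain:
    """Build the standard stimulation train (15 biphasic pulses at 25 Hz).

    Raises
    ------
    SafetyLimitError
        If ``amplitude`` exceeds 3 mA.
    """
    return PulseTrain(
        n_pulses=n,
        pulse_width=width,
        rate=rate,
        amplitude=amplitude,
        onset_re_stimulus=onset_re_stimulus,
    )


def run_staircase(
    observer: Callable[[float], float],
    up: float = 0.1,
    down: float = 0.3,
    stop_reversals: int = 8,
    start_amplitude: float = 0.5,
    seed: int | None = None,
    max_trials: int = 1000,
    use_all_post_first_reversal: bool = False,
) -> StaircaseTrace:
    """Run an asymmetric up/down staircase against a detection model.

    ``observer`` maps amplitude (mA) to detection probability and must be
    monotone non-decreasing.  The amplitude steps up by ``up`` after a miss
    and down by ``down`` after a detection; a reversal is a change of step
    direction.  The run stops once ``stop_reversals`` reversals have
    occurred, and the threshold estimate is the mean amplitude at the
    reversal points (or, with ``use_all_post_first_reversal``, the mean of
    all amplitudes from the first reversal on).

    The stimulation amplitude for the training session is the estimate
    minus 0.2 mA, floored at zero.

    Raises
    ------
    StaircaseConvergenceError
        If ``max_trials`` trials elapse before enough reversals accumulate
        (e.g. a degenerate observer that always or never detects).
    """
    rng = np.random.default_rng(seed)
    amplitudes: list[float] = []
    responses: list[bool] = []
    reversals: list[int] = []
    amp = float(start_amplitude)
    prev_direction = 0  # -1 down, +1 up
    for _ in range(max_trials):
        amp = max(amp, 0.0)
        p = float(observer(amp))
        detected = bool(rng.random() < p)
        amplitudes.append(amp)
        responses.append(detected)
        direction = -1 if detected else +1
        if prev_direction != 0 and direction != prev_direction:
            reversals.append(len(amplitudes) - 1)
            if len(reversals) >= stop_reversals:
                break
        prev_direction = direction
        amp = amp - down if detected else amp + up
    else:
        raise StaircaseConvergenceError(
            f"only {len(reversals)} reversals in {max_trials} trials"
        )

    amps = np.asarray(amplitudes)
    if use_all_post_first_reversal:
        threshold = float(amps[reversals[0] :].mean())
    else:
        threshold = float(amps[reversals].mean())
    return StaircaseTrace(
        amplitudes=amps,
        responses=np.asarray(responses, dtype=bool),
        reversal_indices=reversals,
        threshold_estimate=threshold,
        stim_amplitude=max(threshold - 0.2, 0.0),
    )


def logistic_observer(threshold: float, slope: float = 20.0) -> Callable[[float], float]:
    """Detection model: P(detect | amp) = logistic(slope * (amp - threshold))."""

    def p_detect(amp: float) -> float:
        return 1.0 / (1.0 + np.exp(-slope * (amp - threshold)))

    return p_detect


def step_observer(threshold: float) -> Callable[[float], float]:
    """Deterministic observer detecting iff amplitude >= threshold."""

    def p_detect(amp: float) -> float:
        return 1.0 if amp >= threshold else 0.0

    return p_detect


_CONDITIONS = ("easy", "hard", "feedback", "control")


def assign_stimulation(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Set the ``stimulated`` flag per trial according to the pairing condition.

    ``easy`` pairs stimulation with the perceptually salient tones (T1/T3),
    ``hard`` with T2/T4, ``feedback`` with correct-outcome trials (stimulation
    synchronized with positive feedback), and ``control`` with nothing.
    Generalization-phase trials are never stimulated.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {_CONDITIONS}")
    out = trials.copy()
    training = out["phase"] == "training" if "phase" in out else pd.Series(True, index=out.index)
    if condition == "easy":
        flag = out["tone"].isin(EASY_TONES)
    elif condition == "hard":
        flag = out["tone"].isin(HARD_TONES)
    elif condition == "feedback":
        flag = out["outcome"].astype(bool)
    else:
        flag = pd.Series(False, index=out.index)
    out["stimulated"] = (flag & training).astype(int)
    return out
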