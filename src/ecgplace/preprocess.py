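"""Single-beat preprocessing: amplitude normalization and fiducial delineation.

A *beat* is one cardiac cycle (P wave followed by the QRS complex) from one
precordial lead, sampled at a fixed rate.  Two operations are provided:

``normalize``
    Divides the signal by its maximum absolute amplitude so that
    ``max |y| = 1``.  This is the standard per-beat amplitude normalization
    used to remove gain differences and reduce the influence of baseline
    drift before feature extraction.

``delineate``
    Locates the P peak, QRS onset, R peak, S trough and QRS offset on a
    single beat and derives the landmark amplitudes and the PR interval.
    The R peak is the global absolute extremum; QRS onset/offset are found
    by scanning outward from R for the point where the rectified first
    difference stays below a fraction of its maximum; the P peak is the
    absolute extremum before the QRS; the S trough is the minimum between
    R and the QRS offset.

The PR interval here runs from the P *peak* to the QRS onset (in ms).  P-wave
onset is ill-posed on noisy single beats, while the peak-to-onset distance is
robust and tracks the same physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Beat",
    "FiducialPoints",
    "DegenerateBeatError",
    "DelineationError",
    "normalize",
    "delineate",
]


class DegenerateBeatError(ValueError):
    """Raised for beats on which an operation is mathematically undefined."""


class DelineationError(ValueError):
    """Raised when a fiducial landmark cannot be located on a beat."""


@dataclass(frozen=True)
class Beat:
    """One lead's single-cycle ECG samples.

    Parameters
    ----------
    samples
        Amplitudes in mV, ordered in time.
    fs
        Sampling rate in Hz.
    lead
        Lead identity, ``"V1"`` or ``"V2"``.
    """

    samples: np.ndarray
    fs: float
    lead: str = "V2"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a beat needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("beat samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Beat duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class FiducialPoints:
    """Delineated landmarks of one beat: indices, amplitudes and the PR interval.

    Amplitudes are in mV (read from the beat that was delineated); the PR
    interval is the P-peak-to-QRS-onset distance in ms.
    """

    p_peak_idx: int
    p_amplitude: float
    qrs_onset_idx: int
    qrs_onset_value: float
    r_peak_idx: int
    r_amplitude: float
    qrs_offset_idx: int
    qrs_offset_value: float
    s_trough_idx: int
    s_amplitude: float
    pr_interval: float
    lead: str = field(default="V2", compare=False)

    def __post_init__(self) -> None:
        ordered = (
            self.p_peak_idx
            < self.qrs_onset_idx
            <= self.r_peak_idx
            <= self.s_trough_idx
            <= self.qrs_offset_idx
        )
        if not ordered:
            raise ValueError(
                "fiducial indices out of order: "
                f"P={self.p_peak_idx}, onset={self.qrs_onset_idx}, "
                f"R={self.r_peak_idx}, S={self.s_trough_idx}, "
                f"offset={self.qrs_offset_idx}"
            )
        if self.pr_interval <= 0:
            raise ValueError(f"PR interval must be positive, got {self.pr_interval}")

    def to_json(self) -> str:
        """Serialize the fiducials of one beat as a JSON object string."""
        import dataclasses
        import json

        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def normalize(beat: Beat) -> Beat:
    """Scale a beat so its maximum absolute amplitude is exactly 1.

    ``y[n] = s[n] / max|s[n]|``; the sign pattern and landmark positions are
    preserved (the operation is a positive rescaling).

    Raises
    ------
    DegenerateBeatError
        If the beat is identically zero (the scale factor is undefined).
    """
    peak = np.max(np.abs(beat.samples))
    if peak == 0.0:
        raise DegenerateBeatError("cannot normalize an all-zero beat")
    return replace(beat, samples=beat.samples / peak)


# QRS onset/offset: first sample, scanning outward from R, where the rectified
# first difference stays below DIFF_FRACTION of its max for DIFF_RUN samples.
# The difference signal is computed on a lightly smoothed copy so measurement
# noise does not mask the quiet baseline; if no quiet run exists, the bound
# falls back to a physiological window around R (a QRS complex at 300 Hz is
# well inside +/-120 ms of its R peak).
_DIFF_FRACTION = 0.10
_DIFF_RUN = 3
_SMOOTH_WIDTH = 5  # samples (~17 ms at 300 Hz), centered moving average
_FALLBACK_BEFORE_S = 0.08
_FALLBACK_AFTER_S = 0.12


def _qrs_bounds(samples: np.ndarray, r_idx: int, fs: float) -> tuple[int, int]:
    kernel = np.ones(_SMOOTH_WIDTH) / _SMOOTH_WIDTH
    smooth = np.convolve(samples, kernel, mode="same")
    diff = np.abs(np.diff(smooth))
    thresh = _DIFF_FRACTION * diff.max()

    onset = None
    quiet = 0
    for i in range(r_idx - 1, -1, -1):  # diff[i] spans samples i -> i+1
        if diff[i] < thresh:
            quiet += 1
            if quiet >= _DIFF_RUN:
                onset = i + _DIFF_RUN  # first quiet sample of the run
                break
        else:
            quiet = 0
    if onset is None:
        onset = max(1, r_idx - int(round(_FALLBACK_BEFORE_S * fs)))

    offset = None
    quiet = 0
    for i in range(r_idx, diff.size):
        if diff[i] < thresh:
            quiet += 1
            if quiet >= _DIFF_RUN:
                offset = i - _DIFF_RUN + 1
                break
        else:
            quiet = 0
    if offset is None:
        offset = min(samples.size - 1,
                     r_idx + int(round(_FALLBACK_AFTER_S * fs)))

    return onset, max(offset, r_idx)


def delineate(beat: Beat) -> FiducialPoints:
    """Locate P/QRS landmarks on a single beat.

    The beat must contain exactly one cardiac cycle with PQRS deflections.
    Delineation is scale-invariant, so it may be run before or after
    ``normalize``; amplitudes are read from the beat actually passed in.

    Raises
    ------
    DelineationError
        If the signal is flat (no landmarks exist) or no pre-QRS window is
        available to search for the P wave.
    """
    s = beat.samples
    if np.ptp(s) == 0.0:
        raise DelineationError(f"flat signal on lead {beat.lead}: nothing to delineate")

    r_idx = int(np.argmax(np.abs(s)))
    onset, offset = _qrs_bounds(s, r_idx, beat.fs)
    if onset < 1:
        raise DelineationError(
            f"no pre-QRS window to search for the P wave on lead {beat.lead}"
        )

    # P peak: absolute extremum strictly before QRS onset.
    p_window = s[:onset]
    p_idx = int(np.argmax(np.abs(p_window)))

    # S trough: minimum between R and QRS offset (inclusive).
    s_window = s[r_idx : offset + 1]
    s_idx = r_idx + int(np.argmin(s_window))

    pr_ms = (onset - p_idx) * 1000.0 / beat.fs

    return FiducialPoints(
        p_peak_idx=p_idx,
        p_amplitude=float(s[p_idx]),
        qrs_onset_idx=onset,
        qrs_onset_value=float(s[onset]),
        r_peak_idx=r_idx,
        r_amplitude=float(s[r_idx]),
        qrs_offset_idx=offset,
        qrs_offset_value=float(s[offset]),
        s_trough_idx=s_idx,
        s_amplitude=float(s[s_idx]),
        pr_interval=pr_ms,
        lead=beat.lead,
    )
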