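"""The 16-feature representation of one V1/V2 beat pair.

Features come from three domains:

* time domain (6): P-wave amplitude, PR interval, QRS beginning value,
  R amplitude, end-of-QRS value, S-wave amplitude — read at the delineated
  fiducial points;
* statistical (7): mean, variance, SD, skewness and kurtosis of the
  designated lead, plus the Pearson correlation and root-mean-square error
  between the V1 and V2 signals;
* time-frequency (3): maximum, minimum and mean of the level-4 detail
  coefficients (D4) of a 4-level discrete wavelet transform with a symlet
  mother wavelet.

Single-lead features (f1-f14) are computed on one designated lead
(default V2, the lead most sensitive to vertical misplacement); f15/f16 use
both leads.  Moments use the population (divide-by-n) convention and
kurtosis is the raw standardized fourth moment (Gaussian -> 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .preprocess import (
    Beat,
    DegenerateBeatError,
    FiducialPoints,
    delineate,
    normalize,
)
from .synth import BeatPair, Cohort

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_DESCRIPTIONS",
    "FeatureConfig",
    "FeatureVector",
    "time_domain_features",
    "statistical_features",
    "wavelet_features",
    "pair_features",
    "build_feature_vector",
    "feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 17))

FEATURE_DESCRIPTIONS = {
    "f1": "P-wave amplitude",
    "f2": "PR interval (ms)",
    "f3": "QRS beginning value",
    "f4": "R amplitude",
    "f5": "End of QRS value",
    "f6": "S-wave amplitude",
    "f7": "Mean of ECG signal",
    "f8": "Variance of ECG",
    "f9": "SD of ECG signal",
    "f10": "Skewness of ECG",
    "f11": "Kurtosis of ECG signal",
    "f12": "Maximum value of D4",
    "f13": "Minimum value of D4",
    "f14": "Mean value of D4",
    "f15": "Correlation coefficient between V1 and V2 ECGs",
    "f16": "Root-mean-square error between V1 and V2 ECGs",
}


@dataclass(frozen=True)
class FeatureConfig:
    """Conventions held fixed across a feature-extraction run.

    ``lead`` is the designated lead for the single-lead features f1-f14.
    ``amplitudes_from_normalized`` selects whether the time-domain amplitude
    features are read from the normalized or the raw beat (delineation always
    runs on the raw beat; landmark indices are scale-invariant).
    """

    lead: str = "V2"
    amplitudes_from_normalized: bool = True
    wavelet: str = "sym4"
    dwt_level: int = 4
    dwt_mode: str = "symmetric"


@dataclass(frozen=True)
class FeatureVector:
    """The 16 features of one beat pair, ordered f1..f16."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (16,):
            raise ValueError(f"expected 16 features, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("all features must be finite")

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def time_domain_features(fid: FiducialPoints, beat: Beat) -> np.ndarray:
    """f1-f6: landmark amplitudes and the PR interval.

    ``fid`` must have been delineated from (a rescaling of) ``beat``;
    amplitude values are read at the fiducial indices of the beat passed
    here, so the caller chooses the raw or normalized amplitude convention.
    """
    s = beat.samples
    if fid.qrs_offset_idx >= s.size:
        raise ValueError("fiducial indices exceed beat length")
    return np.array(
        [
            s[fid.p_peak_idx],
            fid.pr_interval,
            s[fid.qrs_onset_idx],
            s[fid.r_peak_idx],
            s[fid.qrs_offset_idx],
            s[fid.s_trough_idx],
        ]
    )


def statistical_features(signal: np.ndarray) -> np.ndarray:
    """f7-f11: mean, population variance, SD, skewness, raw kurtosis."""
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for the moment features")
    var = float(np.var(x))
    if var == 0.0:
        raise DegenerateBeatError(
            "zero-variance signal: skewness and kurtosis are undefined")
    return np.array(
        [
            float(np.mean(x)),
            var,
            float(np.sqrt(var)),
            float(stats.skew(x, bias=True)),
            float(stats.kurtosis(x, fisher=False, bias=True)),
        ]
    )


def _min_dwt_length(wavelet: str, level: int) -> int:
    return (pywt.Wavelet(wavelet).dec_len - 1) * 2**level


def wavelet_features(signal: np.ndarray, config: FeatureConfig = FeatureConfig()
                     ) -> np.ndarray:
    """f12-f14: max, min and mean of the level-4 detail coefficients.

    Uses a ``dwt_level``-level decomposition with the configured symlet and
    symmetric (half-point) boundary extension.
    """
    x = np.asarray(signal, dtype=float)
    min_len = _min_dwt_length(config.wavelet, config.dwt_level)
    if x.size < min_len:
        raise ValueError(
            f"signal of length {x.size} is too short for a "
            f"{config.dwt_level}-level {config.wavelet} transform; "
            f"need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(x, config.wavelet, mode=config.dwt_mode,
                          level=config.dwt_level)
    d4 = coeffs[1]  # [A4, D4, D3, D2, D1]
    return np.array([float(d4.max()), float(d4.min()), float(d4.mean())])


def pair_features(v1_signal: np.ndarray, v2_signal: np.ndarray) -> np.ndarray:
    """f15-f16: Pearson correlation and RMS difference between the two leads."""
    a = np.asarray(v1_signal, dtype=float)
    b = np.asarray(v2_signal, dtype=float)
    if a.shape != b.shape:
        raise ValueError("V1 and V2 signals must have equal length")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise DegenerateBeatError(
            "zero-variance lead: Pearson correlation is undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return np.array([r, rmse])


def build_feature_vector(pair: BeatPair,
                         config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Assemble f1..f16 for one beat pair.

    Delineation runs on the raw designated lead; all other features (and, by
    default, the landmark amplitudes) are computed on the per-lead normalized
    signals.
    """
    designated = pair.v2 if config.lead == "V2" else pair.v1
    fid = delineate(designated)
    norm_designated = normalize(designated)
    amp_beat = norm_designated if config.amplitudes_from_normalized else designated

    f_time = time_domain_features(fid, amp_beat)
    f_stat = statistical_features(norm_designated.samples)
    f_wav = wavelet_features(norm_designated.samples, config)
    f_pair = pair_features(normalize(pair.v1).samples, normalize(pair.v2).samples)

    return FeatureVector(np.concatenate([f_time, f_stat, f_wav, f_pair]))


def feature_matrix(cohort: Cohort,
                   config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Extract features for every pair in a cohort.

    Returns a DataFrame with columns f1..f16, ``label``, ``subject_id`` and
    ``subject_class``, one row per beat pair in cohort order.
    """
    rows = [build_feature_vector(p, config).values for p in cohort.pairs]
    df = pd.DataFrame(np.asarray(rows), columns=list(FEATURE_NAMES))
    df["label"] = cohort.labels
    df["subject_id"] = cohort.subject_ids
    df["subject_class"] = cohort.subject_classes
    return df


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    """Write a feature matrix as CSV at full float precision (lossless)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    return df
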