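"""Synthetic cohorts of paired V1/V2 single beats at correct and misplaced positions.

Vertical misplacement of the V1/V2 chest electrodes (placing them one or two
intercostal spaces too high, i.e. in the 3rd or 2nd ICS instead of the 4th)
changes the morphology of the recorded beat: the R wave attenuates, the P wave
shifts toward zero or negative, the S wave shallows, and a secondary positive
deflection after S can appear (the classic rSr'-type pattern of high
placement).  This module generates labeled cohorts that emulate the end
product of a body-surface-potential-map study of that effect: for each
synthetic subject, one beat pair recorded at the correct position and one at a
vertically displaced position, with the morphology change growing with the
displacement (2nd ICS deltas are twice the 3rd ICS deltas) and an exact 50/50
correct/misplaced label balance.

Each lead's noiseless beat is a sum of Gaussian-shaped waves (P, Q, R, S and,
when misplaced, r'), a standard synthetic-ECG construction that gives
analytically known ground truth for delineation and feature tests.  Gaussian
measurement noise and a low-frequency sinusoidal baseline drift are
superimposed.  Subjects come from three classes — normal, myocardial
infarction (MI: reduced R, deepened Q) and left ventricular hypertrophy
(LVH: enlarged R and S) — with per-subject parameter jitter.

The effect sizes here are free parameters of the generator, not estimates of
any recorded cohort.

Randomness is counter-based: each subject's stream is seeded by
``(seed, class, subject-index)``, so enlarging ``n_per_class`` never
reshuffles earlier subjects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import Beat

__all__ = [
    "SUBJECT_CLASSES",
    "ICS_SEVERITY",
    "CohortConfig",
    "MorphologyParams",
    "BeatPair",
    "Cohort",
    "class_morphology",
    "synthesize_beat_pair",
    "generate_cohort",
    "beat_pair_tensor",
    "write_cohort",
    "read_cohort",
]

SUBJECT_CLASSES = ("normal", "MI", "LVH")

#: Relative severity of the misplacement deltas per displacement condition.
#: Two intercostal spaces too high distorts the beat twice as much as one.
ICS_SEVERITY = {"third": 1.0, "second": 2.0}

_DRIFT_FREQ_HZ = 0.4  # slow baseline wander, well below the cardiac band


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one generated cohort.

    Defaults mirror the emulated study design: 151 subjects in each of three
    diagnostic classes (453 total), single 0.6 s beats at 300 Hz, and one
    correct plus one misplaced recording per subject (906 labeled pairs,
    balanced 50/50).
    """

    n_per_class: int = 151
    classes: tuple[str, ...] = SUBJECT_CLASSES
    ics_level: str = "second"
    fs: float = 300.0
    beat_duration: float = 0.6
    effect_scale: float = 1.0
    noise_sd: float = 0.05
    baseline_drift_amp: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        classes = tuple(self.classes)
        if not classes:
            raise ValueError("classes must be a non-empty subset of "
                             f"{SUBJECT_CLASSES}")
        unknown = set(classes) - set(SUBJECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown subject classes: {sorted(unknown)}")
        object.__setattr__(self, "classes", classes)
        if self.ics_level not in ICS_SEVERITY:
            raise ValueError(f"ics_level must be one of {sorted(ICS_SEVERITY)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.beat_duration <= 0:
            raise ValueError("beat_duration must be positive")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_drift_amp < 0:
            raise ValueError("baseline_drift_amp must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.beat_duration))

    @property
    def n_subjects(self) -> int:
        return self.n_per_class * len(self.classes)


@dataclass(frozen=True)
class MorphologyParams:
    """Ground-truth waveform parameters for one subject.

    Amplitudes in mV, centers and widths in seconds, for the designated (V2)
    lead; V1 is the same shape scaled by ``v1_gain``.  The misplacement deltas
    are per unit ``effect_scale`` at severity 1 (3rd ICS); the 2nd ICS applies
    them with severity 2.
    """

    p_amp: float = 0.15
    q_amp: float = -0.10
    r_amp: float = 1.20
    s_amp: float = -0.50
    p_center: float = 0.12
    q_center: float = 0.26
    r_center: float = 0.30
    s_center: float = 0.36
    p_width: float = 0.025
    q_width: float = 0.010
    r_width: float = 0.014
    s_width: float = 0.014
    v1_gain: float = 0.75
    # misplacement deltas (per unit effect_scale, severity 1)
    r_attenuation: float = 0.045
    p_shift: float = 0.024
    s_attenuation: float = 0.036
    rprime_amp: float = 0.036
    rprime_center: float = 0.40
    rprime_width: float = 0.012

    def __post_init__(self) -> None:
        widths = (self.p_width, self.q_width, self.r_width, self.s_width,
                  self.rprime_width)
        if any(w <= 0 for w in widths):
            raise ValueError("wave widths must be positive")
        centers = (self.p_center, self.q_center, self.r_center, self.s_center,
                   self.rprime_center)
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError(
                "wave centers must be ordered P < Q < R < S < r', got "
                f"{centers}"
            )

    def misplaced(self, severity: float, effect_scale: float) -> "MorphologyParams":
        """Morphology after vertical displacement at the given severity.

        At ``effect_scale == 0`` this is the identity.  Attenuation factors
        are floored at 0.05 so extreme effect scales shrink waves toward zero
        rather than flipping their sign.
        """
        e = severity * effect_scale
        r_factor = max(1.0 - self.r_attenuation * e, 0.05)
        s_factor = max(1.0 - self.s_attenuation * e, 0.05)
        return dataclasses.replace(
            self,
            r_amp=self.r_amp * r_factor,
            s_amp=self.s_amp * s_factor,
            p_amp=self.p_amp - self.p_shift * e,
        )


@dataclass(frozen=True)
class BeatPair:
    """Simultaneous V1 and V2 beats for one subject at one electrode position."""

    v1: Beat
    v2: Beat
    placement_label: int  # 1 = correct (4th ICS), 0 = misplaced
    ics_level: str  # fourth | third | second
    subject_class: str
    subject_id: str
    ground_truth: MorphologyParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.v1) != len(self.v2) or self.v1.fs != self.v2.fs:
            raise ValueError("V1 and V2 beats must share length and sampling rate")
        if self.placement_label not in (0, 1):
            raise ValueError("placement_label must be 0 or 1")
        if (self.placement_label == 1) != (self.ics_level == "fourth"):
            raise ValueError(
                "placement_label 1 must coincide with ics_level 'fourth' "
                f"(got label={self.placement_label}, ics={self.ics_level})"
            )


@dataclass(frozen=True)
class Cohort:
    """A labeled synthetic dataset of beat pairs plus the config that made it."""

    pairs: tuple[BeatPair, ...]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.placement_label for p in self.pairs], dtype=int)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(p.subject_id for p in self.pairs)

    @property
    def subject_classes(self) -> tuple[str, ...]:
        return tuple(p.subject_class for p in self.pairs)


# Per-class multipliers on (P, Q, R, S) amplitudes.  LVH enlarges the QRS;
# MI shrinks R and deepens Q.  Package defaults, not cohort estimates.
_CLASS_AMP_FACTORS = {
    "normal": (1.0, 1.0, 1.0, 1.0),
    "MI": (1.0, 2.5, 0.55, 0.8),
    "LVH": (1.0, 1.0, 1.5, 1.4),
}

# Amplitude variation across subjects is mostly a common gain (electrode
# contact, body habitus), with only mild independent per-wave variation, so
# the R/S amplitude ratio stays stable within a class.
_SIZE_JITTER_SD = 0.15  # lognormal sigma of the shared beat-size factor
_AMP_JITTER_SD = 0.07   # lognormal sigma of per-wave amplitude factors
_CENTER_JITTER_SD = 0.004  # seconds, whole-complex timing shift
_WIDTH_JITTER_SD = 0.06  # lognormal sigma on wave widths


def class_morphology(subject_class: str, rng: np.random.Generator) -> MorphologyParams:
    """Draw one subject's morphology from the class-conditioned distribution."""
    if subject_class not in _CLASS_AMP_FACTORS:
        raise ValueError(f"unknown subject class {subject_class!r}")
    base = MorphologyParams()
    fp, fq, fr, fs_ = _CLASS_AMP_FACTORS[subject_class]
    size = np.exp(rng.normal(0.0, _SIZE_JITTER_SD))
    amp_jit = size * np.exp(rng.normal(0.0, _AMP_JITTER_SD, size=4))
    shift = rng.normal(0.0, _CENTER_JITTER_SD)  # whole-complex timing jitter
    width_jit = np.exp(rng.normal(0.0, _WIDTH_JITTER_SD, size=4))
    return dataclasses.replace(
        base,
        p_amp=base.p_amp * fp * amp_jit[0],
        q_amp=base.q_amp * fq * amp_jit[1],
        r_amp=base.r_amp * fr * amp_jit[2],
        s_amp=base.s_amp * fs_ * amp_jit[3],
        p_center=base.p_center + shift,
        q_center=base.q_center + shift,
        r_center=base.r_center + shift,
        s_center=base.s_center + shift,
        rprime_center=base.rprime_center + shift,
        p_width=base.p_width * width_jit[0],
        q_width=base.q_width * width_jit[1],
        r_width=base.r_width * width_jit[2],
        s_width=base.s_width * width_jit[3],
    )


# V1 is not a pure rescaling of V2: per-wave relative factors (on top of the
# overall v1_gain) give it a distinct shape — relatively smaller P, deeper
# Q/S (the rS pattern of V1) and a more prominent r' under high placement —
# so the inter-lead correlation and RMS-difference features are informative.
_V1_WAVE_FACTORS = {"P": 0.8, "Q": 1.1, "R": 1.0, "S": 1.2, "rprime": 1.6}
_V2_WAVE_FACTORS = {"P": 1.0, "Q": 1.0, "R": 1.0, "S": 1.0, "rprime": 1.0}


def _gaussian_sum(t: np.ndarray, morph: MorphologyParams,
                  gain: float, rprime_amp: float,
                  wave_factors: dict[str, float]) -> np.ndarray:
    waves = [
        ("P", morph.p_amp, morph.p_center, morph.p_width),
        ("Q", morph.q_amp, morph.q_center, morph.q_width),
        ("R", morph.r_amp, morph.r_center, morph.r_width),
        ("S", morph.s_amp, morph.s_center, morph.s_width),
        ("rprime", rprime_amp, morph.rprime_center, morph.rprime_width),
    ]
    y = np.zeros_like(t)
    for name, amp, center, width in waves:
        amp = amp * wave_factors[name]
        if amp != 0.0:
            y += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return gain * y


def synthesize_beat_pair(
    subject_class: str,
    placement: str,
    morph: MorphologyParams,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "s0",
) -> BeatPair:
    """Render one V1+V2 beat pair at the given electrode placement.

    ``placement`` is ``"correct"`` or ``"misplaced"``; a misplaced pair uses
    the displacement condition in ``config.ics_level`` with its deltas scaled
    by ``config.effect_scale``.  With the same ``rng`` state the output is
    bit-reproducible.
    """
    if placement not in ("correct", "misplaced"):
        raise ValueError("placement must be 'correct' or 'misplaced'")
    n = config.n_samples
    if n < 2:
        raise ValueError("fs x beat_duration must give at least 2 samples")
    t = np.arange(n) / config.fs

    if placement == "misplaced":
        severity = ICS_SEVERITY[config.ics_level]
        eff = morph.misplaced(severity, config.effect_scale)
        rprime = morph.rprime_amp * severity * config.effect_scale
        ics = config.ics_level
        label = 0
    else:
        eff = morph
        rprime = 0.0
        ics = "fourth"
        label = 1

    beats = {}
    for lead, gain, factors in (("V1", morph.v1_gain, _V1_WAVE_FACTORS),
                                ("V2", 1.0, _V2_WAVE_FACTORS)):
        clean = _gaussian_sum(t, eff, gain, rprime, factors)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        drift = config.baseline_drift_amp * np.sin(
            2.0 * np.pi * _DRIFT_FREQ_HZ * t + phase)
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 \
            else np.zeros(n)
        beats[lead] = Beat(clean + drift + noise, fs=config.fs, lead=lead)

    return BeatPair(
        v1=beats["V1"],
        v2=beats["V2"],
        placement_label=label,
        ics_level=ics,
        subject_class=subject_class,
        subject_id=subject_id,
        ground_truth=morph,
    )


def _subject_rng(seed: int, class_idx: int, subject_idx: int) -> np.random.Generator:
    # Counter-based stream: keyed by (seed, class, subject), so cohort size
    # changes never reshuffle earlier subjects.
    return np.random.default_rng([seed, class_idx, subject_idx])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full labeled cohort for one displacement condition.

    Every subject contributes exactly one correct and one misplaced pair, so
    the label balance is exactly 50/50.  Deterministic given ``config.seed``.
    """
    pairs: list[BeatPair] = []
    for class_idx, subject_class in enumerate(config.classes):
        global_class_idx = SUBJECT_CLASSES.index(subject_class)
        for i in range(config.n_per_class):
            rng = _subject_rng(config.seed, global_class_idx, i)
            morph = class_morphology(subject_class, rng)
            sid = f"{subject_class}_{i:04d}"
            for placement in ("correct", "misplaced"):
                pairs.append(
                    synthesize_beat_pair(
                        subject_class, placement, morph, config, rng,
                        subject_id=sid,
                    )
                )
    return Cohort(pairs=tuple(pairs), config=config)


def beat_pair_tensor(pairs: Sequence[BeatPair]) -> np.ndarray:
    """Stack pairs into an (n, 2, T) array (channel 0 = V1, channel 1 = V2)."""
    return np.stack([np.stack([p.v1.samples, p.v2.samples]) for p in pairs])


# ---------------------------------------------------------------------------
# On-disk format: one CSV (time_s, v1_mV, v2_mV) + one JSON sidecar per pair.

def _pair_stem(pair: BeatPair) -> str:
    return f"{pair.subject_id}_{'correct' if pair.placement_label else 'misplaced'}"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as per-pair CSV + JSON files and a manifest.

    The text output is byte-stable for a fixed config (fixed float formats,
    sorted JSON keys), so repeated runs with the same seed serialize
    identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stems = []
    for pair in cohort.pairs:
        stem = _pair_stem(pair)
        stems.append(stem)
        t = pair.v1.times
        with open(out / f"{stem}.csv", "w") as fh:
            fh.write("time_s,v1_mV,v2_mV\n")
            for ti, a, b in zip(t, pair.v1.samples, pair.v2.samples):
                fh.write(f"{ti:.9g},{a:.9g},{b:.9g}\n")
        meta = {
            "subject_id": pair.subject_id,
            "subject_class": pair.subject_class,
            "placement_label": pair.placement_label,
            "ics_level": pair.ics_level,
            "fs": pair.v1.fs,
            "n_samples": len(pair.v1),
        }
        with open(out / f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
    manifest = {
        "pairs": stems,
        "config": dataclasses.asdict(cohort.config),
    }
    with open(out / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`.

    Ground-truth morphology is not serialized, so round-tripped pairs carry
    ``ground_truth=None``.
    """
    src = Path(in_dir)
    with open(src / "cohort.json") as fh:
        manifest = json.load(fh)
    cfg_dict = manifest["config"]
    cfg_dict["classes"] = tuple(cfg_dict["classes"])
    config = CohortConfig(**cfg_dict)
    pairs = []
    for stem in manifest["pairs"]:
        with open(src / f"{stem}.json") as fh:
            meta = json.load(fh)
        data = np.genfromtxt(src / f"{stem}.csv", delimiter=",", names=True)
        v1 = Beat(np.atleast_1d(data["v1_mV"]), fs=meta["fs"], lead="V1")
        v2 = Beat(np.atleast_1d(data["v2_mV"]), fs=meta["fs"], lead="V2")
        pairs.append(
            BeatPair(
                v1=v1,
                v2=v2,
                placement_label=meta["placement_label"],
                ics_level=meta["ics_level"],
                subject_class=meta["subject_class"],
                subject_id=meta["subject_id"],
            )
        )
    return Cohort(pairs=tuple(pairs), config=config)
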