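"""Synthetic cohort generator: contracts, determinism, effect structure."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest

from ecgplace import (
    Beat,
    BeatPair,
    CohortConfig,
    MorphologyParams,
    beat_pair_tensor,
    generate_cohort,
    read_cohort,
    synthesize_beat_pair,
    write_cohort,
)
from ecgplace.synth import ICS_SEVERITY, class_morphology


def _quiet_config(**kw):
    defaults = dict(n_per_class=2, noise_sd=0.0, baseline_drift_amp=0.0, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestBeatPairSynthesis:
    def test_zero_effect_misplaced_beat_is_sample_identical(self):
        cfg = _quiet_config(effect_scale=0.0)
        morph = MorphologyParams()
        a = synthesize_beat_pair("normal", "correct", morph, cfg,
                                 np.random.default_rng(7))
        b = synthesize_beat_pair("normal", "misplaced", morph, cfg,
                                 np.random.default_rng(7))
        np.testing.assert_array_equal(a.v2.samples, b.v2.samples)
        np.testing.assert_array_equal(a.v1.samples, b.v1.samples)

    def test_single_r_wave_peaks_at_r_center_with_r_amplitude(self):
        cfg = _quiet_config()
        morph = MorphologyParams(p_amp=0.0, q_amp=0.0, s_amp=0.0, r_amp=0.9)
        pair = synthesize_beat_pair("normal", "correct", morph, cfg,
                                    np.random.default_rng(0))
        peak_idx = int(np.argmax(pair.v2.samples))
        assert abs(peak_idx - morph.r_center * cfg.fs) <= 1
        assert pair.v2.samples[peak_idx] == pytest.approx(0.9, abs=0.01)

    def test_fixed_seed_gives_bit_identical_pairs(self):
        cfg = CohortConfig(n_per_class=1, seed=5)
        morph = MorphologyParams()
        runs = [synthesize_beat_pair("MI", "misplaced", morph, cfg,
                                     np.random.default_rng(99))
                for _ in range(2)]
        np.testing.assert_array_equal(runs[0].v1.samples, runs[1].v1.samples)
        np.testing.assert_array_equal(runs[0].v2.samples, runs[1].v2.samples)

    def test_beat_length_is_fs_times_duration(self):
        cfg = _quiet_config(fs=250.0, beat_duration=0.8)
        pair = synthesize_beat_pair("LVH", "correct", MorphologyParams(), cfg,
                                    np.random.default_rng(0))
        assert len(pair.v1) == len(pair.v2) == 200

    def test_invalid_wave_ordering_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            MorphologyParams(q_center=0.35)  # Q after R

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            MorphologyParams(r_width=0.0)


class TestCohortContract:
    def test_small_cohort_counts_and_balance(self):
        cohort = generate_cohort(_quiet_config(n_per_class=2))
        assert len(cohort) == 12  # 6 subjects x 2 placements
        assert cohort.labels.sum() == 6
        assert len(set(cohort.subject_ids)) == 6

    def test_label_balance_is_exactly_half(self, noisy_cohort):
        assert noisy_cohort.labels.mean() == 0.5

    def test_placement_label_matches_ics_level(self, noisy_cohort):
        for pair in noisy_cohort.pairs:
            assert (pair.placement_label == 1) == (pair.ics_level == "fourth")

    def test_empty_classes_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            CohortConfig(classes=())

    def test_same_seed_identical_different_seed_differs(self):
        cfg = CohortConfig(n_per_class=2, seed=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        c = generate_cohort(dataclasses.replace(cfg, seed=4))
        np.testing.assert_array_equal(beat_pair_tensor(a.pairs),
                                      beat_pair_tensor(b.pairs))
        assert not np.array_equal(beat_pair_tensor(a.pairs),
                                  beat_pair_tensor(c.pairs))

    def test_growing_cohort_preserves_earlier_subjects(self):
        small = generate_cohort(CohortConfig(n_per_class=2, seed=8))
        large = generate_cohort(CohortConfig(n_per_class=4, seed=8))
        by_key = {(p.subject_id, p.placement_label): p for p in large.pairs}
        for p in small.pairs:
            q = by_key[(p.subject_id, p.placement_label)]
            np.testing.assert_array_equal(p.v2.samples, q.v2.samples)


class TestEffectStructure:
    def test_second_ics_deltas_dominate_third(self):
        morph = MorphologyParams()
        third = morph.misplaced(ICS_SEVERITY["third"], 1.0)
        second = morph.misplaced(ICS_SEVERITY["second"], 1.0)
        assert abs(morph.r_amp - second.r_amp) > abs(morph.r_amp - third.r_amp)
        assert abs(morph.s_amp - second.s_amp) > abs(morph.s_amp - third.s_amp)
        assert abs(morph.p_amp - second.p_amp) > abs(morph.p_amp - third.p_amp)

    def test_misplacement_identity_at_zero_effect(self):
        morph = MorphologyParams()
        assert morph.misplaced(2.0, 0.0) == morph

    @pytest.mark.parametrize("ics", ["third", "second"])
    def test_r_amplitude_separation_grows_with_effect_scale(self, ics):
        # Bhattacharyya-style separation of the ground-truth R amplitudes
        def separation(effect_scale):
            sev = ICS_SEVERITY[ics]
            rng = np.random.default_rng(30)
            correct, misplaced = [], []
            for cls in ("normal", "MI", "LVH"):
                for _ in range(30):
                    m = class_morphology(cls, rng)
                    correct.append(m.r_amp)
                    misplaced.append(m.misplaced(sev, effect_scale).r_amp)
            correct, misplaced = np.array(correct), np.array(misplaced)
            pooled = np.sqrt((correct.var() + misplaced.var()) / 2)
            return (correct.mean() - misplaced.mean()) / pooled

        seps = [separation(e) for e in (0.25, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(seps, seps[1:]))

    def test_second_ics_separation_exceeds_third_at_equal_effect(self):
        cfgs = {ics: CohortConfig(n_per_class=25, ics_level=ics, noise_sd=0.0,
                                  baseline_drift_amp=0.0, seed=77)
                for ics in ("second", "third")}
        seps = {}
        for ics, cfg in cfgs.items():
            cohort = generate_cohort(cfg)
            r_amp = np.array([np.max(np.abs(p.v2.samples))
                              for p in cohort.pairs])
            y = cohort.labels
            pooled = np.sqrt((r_amp[y == 1].var() + r_amp[y == 0].var()) / 2)
            seps[ics] = (r_amp[y == 1].mean() - r_amp[y == 0].mean()) / pooled
        assert seps["second"] > seps["third"] > 0


class TestSerialization:
    def test_round_trip_preserves_labels_and_metadata(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_per_class=2, seed=6))
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert back.config == cohort.config
        assert back.subject_ids == cohort.subject_ids
        np.testing.assert_array_equal(back.labels, cohort.labels)
        np.testing.assert_allclose(beat_pair_tensor(back.pairs),
                                   beat_pair_tensor(cohort.pairs), atol=1e-8)

    def test_serialization_is_byte_identical_across_runs(self, tmp_path):
        cfg = CohortConfig(n_per_class=2, seed=9)
        dirs = []
        for name in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / name)
            dirs.append(tmp_path / name)
        files_a = sorted(p.name for p in dirs[0].iterdir())
        files_b = sorted(p.name for p in dirs[1].iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()


class TestBeatPairValidation:
    def test_mismatched_lead_lengths_rejected(self):
        v1 = Beat(np.zeros(10) + [0, 1, 0, 0, 0, 0, 0, 0, 0, 0], 300.0, "V1")
        v2 = Beat(np.ones(12), 300.0, "V2")
        with pytest.raises(ValueError, match="length"):
            BeatPair(v1=v1, v2=v2, placement_label=1, ics_level="fourth",
                     subject_class="normal", subject_id="s")

    def test_label_ics_inconsistency_rejected(self):
        v = Beat(np.arange(10, dtype=float), 300.0)
        with pytest.raises(ValueError, match="ics"):
            BeatPair(v1=v, v2=v, placement_label=1, ics_level="second",
                     subject_class="normal", subject_id="s")
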