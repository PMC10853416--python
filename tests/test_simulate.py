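"""Design generation, signal synthesis, and known-truth effect injection."""

import numpy as np
import pytest

from eegfiction.io import ContractError, TEXT_TYPES
from eegfiction.simulate import (
    DesignSpec,
    EffectSpec,
    NoiseSpec,
    effective_band_powers,
    generate_design,
    scaled_group_sizes,
    small_montage,
    synthesize_recording,
    truth_table,
)
from eegfiction.spectral import BAND_NAMES

from conftest import small_design


class TestGenerateDesign:
    def test_default_design_gives_150_stimuli_120_15_15(self):
        design = generate_design(DesignSpec())
        assert len(design) == 40
        for _, schedule in design:
            types = [s.text_type for s in schedule]
            assert len(types) == 150
            assert types.count("original") == 120
            assert types.count("fanfiction") == 15
            assert types.count("badfiction") == 15

    def test_zero_trials_empty_schedule(self):
        _, schedule = generate_design(DesignSpec(n_trials=0))[0]
        assert schedule == []

    def test_two_trials_follow_pattern_counts(self):
        _, schedule = generate_design(DesignSpec(n_trials=2))[0]
        types = [s.text_type for s in schedule]
        assert (len(types), types.count("original")) == (20, 16)
        assert types.count("fanfiction") == types.count("badfiction") == 2

    def test_default_group_sizes_match_study_counts(self):
        metas = [m for m, _ in generate_design(DesignSpec())]
        counts = {
            var: {}
            for var in (
                "reading_frequency", "fantasy_reader", "hp_fan",
                "literary_familiarity", "badfiction_attitude",
            )
        }
        for m in metas:
            for var in counts:
                lvl = m.level(var)
                counts[var][lvl] = counts[var].get(lvl, 0) + 1
        assert counts["reading_frequency"] == {
            "frequent": 10, "non_frequent": 10, "rest": 20
        }
        assert counts["fantasy_reader"] == {"fantasy": 26, "non_fantasy": 14}
        assert counts["hp_fan"] == {"fan": 17, "non_fan": 23}
        assert counts["literary_familiarity"] == {
            "buff": 12, "rookie": 14, "rest": 14
        }
        assert counts["badfiction_attitude"] == {
            "positive": 9, "negative": 8, "rest": 23
        }

    def test_oversized_groups_rejected(self):
        with pytest.raises(ContractError):
            DesignSpec(
                n_participants=5,
                group_sizes={"hp_fan": {"fan": 4, "non_fan": 4}},
            )

    def test_deterministic_under_seed(self):
        a = generate_design(small_design())
        b = generate_design(small_design())
        assert [m for m, _ in a] == [m for m, _ in b]
        assert [s for _, s in a] == [s for _, s in b]


class TestSynthesize:
    def test_same_seed_bit_identical_samples(self):
        spec = small_design(n_participants=1, n_trials=1, montage_size=4)
        meta, sched = generate_design(spec)[0]
        r1 = synthesize_recording(meta, sched, spec)
        r2 = synthesize_recording(meta, sched, spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_adding_participants_never_perturbs_earlier_ones(self):
        s2 = small_design(n_participants=2, n_trials=1, montage_size=4)
        s3 = small_design(n_participants=3, n_trials=1, montage_size=4)
        # keep the same group sizes so labels for P001 coincide
        s3 = DesignSpec(
            **{
                **{f: getattr(s3, f) for f in (
                    "n_participants", "n_trials", "trial_pattern",
                    "stimulus_duration_s", "gap_s", "sampling_rate_hz",
                    "montage", "noise", "effects", "oscillator", "bands",
                    "base_band_power_uv2", "seed",
                )},
                "group_sizes": s2.group_sizes,
            }
        )
        r2 = synthesize_recording(*generate_design(s2)[0], s2)
        r3 = synthesize_recording(*generate_design(s3)[0], s3)
        np.testing.assert_array_equal(r2.samples, r3.samples)

    def test_pure_alpha_tone_concentrates_power(self):
        """Silent noise + a single alpha oscillator: a direct periodogram of
        the stimulus interval puts >99% of its power in 8-13 Hz."""
        spec = small_design(
            n_participants=1, n_trials=1, montage_size=4,
            trial_pattern=("original",),
            noise=NoiseSpec.silent(),
            oscillator="tone",
            base_band_power_uv2={
                "delta": 0.0, "theta": 0.0, "alpha": 64.0,
                "beta": 0.0, "gamma": 0.0,
            },
        )
        meta, sched = generate_design(spec)[0]
        rec = synthesize_recording(meta, sched, spec)
        ev = rec.events[0]
        fs = rec.sampling_rate_hz
        seg = rec.samples[
            0, int(ev.onset_s * fs) : int((ev.onset_s + ev.duration_s) * fs)
        ]
        freqs = np.fft.rfftfreq(len(seg), 1 / fs)
        # Hann taper controls the leakage of the non-bin-centered tone
        power = np.abs(np.fft.rfft(seg * np.hanning(len(seg)))) ** 2
        in_alpha = power[(freqs > 8) & (freqs <= 13)].sum()
        assert in_alpha / power[freqs > 0].sum() > 0.99

    def test_absolute_scale_effect_recovers_generator_truth_ratio(self):
        """Badfiction beta power scaled 0.5x: the measured badfiction/original
        beta ratio matches the generator's own bookkeeping within sampling
        error."""
        spec = small_design(
            n_participants=1, n_trials=5, montage_size=4,
            duration=(3.0, 4.0),
            noise=NoiseSpec(pink_scale_uv=0.5, sensor_white_uv=0.5,
                            blink_rate_hz=0.0, muscle_burst_rate_hz=0.0),
            effects=(
                EffectSpec("text_type", "badfiction", "beta",
                           "absolute_scale", 0.5),
            ),
        )
        meta, sched = generate_design(spec)[0]
        rec = synthesize_recording(meta, sched, spec)
        fs = rec.sampling_rate_hz

        def beta_power(ev):
            seg = rec.samples[
                0, int(ev.onset_s * fs) : int((ev.onset_s + ev.duration_s) * fs)
            ]
            freqs = np.fft.rfftfreq(len(seg), 1 / fs)
            p = np.abs(np.fft.rfft(seg)) ** 2 / len(seg) ** 2 * 2
            return p[(freqs > 13) & (freqs <= 30)].sum()

        bad = np.mean([beta_power(e) for e in rec.events if e.text_type == "badfiction"])
        orig = np.mean([beta_power(e) for e in rec.events if e.text_type == "original"])
        truth_bad = effective_band_powers(meta, "badfiction", spec)[0, 3]
        truth_orig = effective_band_powers(meta, "original", spec)[0, 3]
        assert truth_bad / truth_orig == pytest.approx(0.5)
        assert bad / orig == pytest.approx(truth_bad / truth_orig, rel=0.35)

    def test_effect_monotonicity_in_expectation(self):
        """A larger absolute_scale strictly increases the measured band power
        averaged over >= 100 segments."""
        means = []
        for mag in (1.0, 2.0):
            spec = small_design(
                n_participants=1, n_trials=10, montage_size=4,
                duration=(2.0, 2.5),
                noise=NoiseSpec.silent(),
                effects=(
                    EffectSpec("text_type", "original", "beta",
                               "absolute_scale", mag),
                ),
            )
            meta, sched = generate_design(spec)[0]
            rec = synthesize_recording(meta, sched, spec)
            fs = rec.sampling_rate_hz
            powers = []
            for ev in rec.events:
                if ev.text_type != "original":
                    continue
                seg = rec.samples[
                    0,
                    int(ev.onset_s * fs) : int((ev.onset_s + ev.duration_s) * fs),
                ]
                freqs = np.fft.rfftfreq(len(seg), 1 / fs)
                p = np.abs(np.fft.rfft(seg)) ** 2
                powers.append(p[(freqs > 13) & (freqs <= 30)].sum() / len(seg))
            assert len(powers) >= 80
            means.append(np.mean(powers))
        assert means[1] > means[0]

    def test_unknown_band_or_channel_in_effect_rejected(self):
        with pytest.raises(ContractError):
            EffectSpec("text_type", "badfiction", "sigma")
        spec = small_design(
            n_participants=1, n_trials=1, montage_size=4,
            effects=(
                EffectSpec("text_type", "badfiction", "beta",
                           "absolute_scale", 0.5, ("Nope",)),
            ),
        )
        meta, sched = generate_design(spec)[0]
        with pytest.raises(ContractError):
            synthesize_recording(meta, sched, spec)


class TestTruthTable:
    def test_no_effects_identical_across_text_types(self):
        spec = small_design(n_participants=2, montage_size=4)
        tt = truth_table(spec)
        pivot = tt.pivot_table(
            index=["participant_id", "channel", "band"],
            columns="text_type",
            values="rel_power",
        )
        for a, b in [("original", "fanfiction"), ("original", "badfiction")]:
            np.testing.assert_allclose(pivot[a], pivot[b])

    def test_relative_shift_raises_target_group_by_stated_amount(self):
        spec = small_design(
            n_participants=4, montage_size=4,
            effects=(
                EffectSpec("group_variable", "non_frequent", "delta",
                           "relative_shift", 0.1),
            ),
        )
        tt = truth_table(spec)
        metas = {m.participant_id: m for m, _ in generate_design(spec)}
        tt["group"] = tt.participant_id.map(
            lambda p: metas[p].level("reading_frequency")
        )
        delta = tt[(tt.band == "delta") & (tt.text_type == "original")]
        by = delta.groupby("group")["rel_power"].mean()
        assert by["non_frequent"] - by["frequent"] == pytest.approx(0.1)

    def test_absolute_scale_renormalizes_relative_powers_to_one(self):
        spec = small_design(
            n_participants=1, montage_size=4,
            effects=(
                EffectSpec("text_type", "badfiction", "beta",
                           "absolute_scale", 0.5),
            ),
        )
        tt = truth_table(spec)
        sums = tt.groupby(["participant_id", "text_type", "channel"])[
            "rel_power"
        ].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)
        # closed form: scaling beta by s rescales every relative power by
        # total/(total - (1-s) * beta)
        base = np.array(
            [spec.base_band_power_uv2[b] for b in BAND_NAMES]
        )
        total = base.sum()
        expected_alpha = base[2] / (total - 0.5 * base[3])
        got = tt[
            (tt.text_type == "badfiction") & (tt.band == "alpha")
        ].rel_power.iloc[0]
        assert got == pytest.approx(expected_alpha)

    def test_relative_shift_outside_unit_interval_rejected(self):
        spec = small_design(
            n_participants=1, montage_size=4,
            effects=(
                EffectSpec("text_type", "badfiction", "alpha",
                           "relative_shift", 0.9),
            ),
        )
        with pytest.raises(ContractError):
            truth_table(spec)


def test_scaled_group_sizes_cover_binary_variables():
    for n in (2, 6, 10, 20, 40):
        gs = scaled_group_sizes(n)
        assert sum(gs["fantasy_reader"].values()) == n
        assert sum(gs["hp_fan"].values()) == n
        for var, sizes in gs.items():
            assert sum(sizes.values()) <= n
    assert scaled_group_sizes(40) == {
        "reading_frequency": {"frequent": 10, "non_frequent": 10},
        "literary_familiarity": {"buff": 12, "rookie": 14},
        "fantasy_reader": {"fantasy": 26, "non_fantasy": 14},
        "hp_fan": {"fan": 17, "non_fan": 23},
        "badfiction_attitude": {"positive": 9, "negative": 8},
    }
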