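"""Simulator: spectral profiles, determinism, band purity, learner dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofb import (
    BandDefinition,
    default_scheme,
    dft_band_power_oracle,
    generate_segment,
    make_pain_profile,
    make_painfree_profile,
    relax_model,
    step_learner,
)
from neurofb.feedback import RegulationDecision
from neurofb.synthsig import (
    BAND_RANGES,
    REINFORCED_BANDS,
    SUPPRESSED_BANDS,
    ParticipantModel,
    expected_band_power,
)


def _decision(success: bool) -> RegulationDecision:
    return RegulationDecision(
        epoch_index=0,
        band_names=("theta", "smr", "high_beta"),
        regulated=(success,) * 3,
        all_regulated=success,
        feedback_level=1.0 if success else 0.0,
    )


class TestProfiles:
    def test_pain_profile_shifts_bands_in_documented_directions(self):
        pain = make_pain_profile(1)
        free = make_painfree_profile(1)
        for band in SUPPRESSED_BANDS:  # theta, high_beta: elevated in pain
            assert pain.band_amplitudes[band] > free.band_amplitudes[band]
        for band in REINFORCED_BANDS:  # high_alpha, low_beta: reduced in pain
            assert pain.band_amplitudes[band] < free.band_amplitudes[band]

    def test_profiles_deterministic_across_seeds(self):
        # the seed is stored for downstream generation only
        assert (
            make_pain_profile(1).band_amplitudes
            == make_pain_profile(2).band_amplitudes
        )

    def test_painfree_amplitudes_positive_and_defaults(self):
        free = make_painfree_profile(0)
        assert all(a > 0 for a in free.band_amplitudes.values())
        assert free.pink_noise_exponent == 1.0
        assert free.responsiveness == 0.0

    def test_pain_resting_theta_power_exceeds_painfree(self):
        # Monte-Carlo over 20 seeds with the DFT oracle as the judge
        theta = BandDefinition("theta", 4.0, 7.0, "suppress")
        diffs = []
        for seed in range(20):
            p = generate_segment(make_pain_profile(seed), 20.0, seed=seed)
            f = generate_segment(make_painfree_profile(seed), 20.0, seed=seed)
            diffs.append(
                dft_band_power_oracle(p, theta).mean()
                - dft_band_power_oracle(f, theta).mean()
            )
        assert np.mean(diffs) > 0

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError, match="amplitude"):
            ParticipantModel(band_amplitudes={"theta": -1.0})
        with pytest.raises(ValueError, match="exponent"):
            make_painfree_profile(0, pink_noise_exponent=3.0)
        with pytest.raises(ValueError, match="responsiveness"):
            make_painfree_profile(0, responsiveness=1.5)


class TestGenerateSegment:
    def test_silent_model_yields_zero_segment(self):
        model = make_painfree_profile(
            0,
            band_amplitudes={b: 0.0 for b in BAND_RANGES},
            pink_noise_scale=0.0,
            artifact_rate=0.0,
        )
        seg = generate_segment(model, 2.0, seed=0)
        assert np.all(seg.data == 0.0)

    def test_sample_count_is_duration_times_fs(self):
        seg = generate_segment(make_pain_profile(0), 120.0, fs=250.0, seed=0)
        assert seg.n_samples == 30_000
        assert seg.channels == ("C3", "C4")

    def test_bit_identical_for_same_seed(self):
        m = make_pain_profile(5)
        a = generate_segment(m, 3.0, seed=42)
        b = generate_segment(m, 3.0, seed=42)
        c = generate_segment(m, 3.0, seed=43)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_rejects_bad_duration_and_rate(self):
        m = make_pain_profile(0)
        with pytest.raises(ValueError, match="duration"):
            generate_segment(m, 0.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist|fs"):
            generate_segment(m, 1.0, fs=50.0, seed=0)

    @pytest.mark.parametrize("band", sorted(BAND_RANGES))
    def test_single_band_concentrates_power(self, band):
        # ≥ 90 % of total (Parseval) power inside the band, by brute-force DFT
        model = make_painfree_profile(
            0,
            band_amplitudes={b: (5.0 if b == band else 0.0) for b in BAND_RANGES},
            pink_noise_scale=0.0,
            artifact_rate=0.0,
        )
        seg = generate_segment(model, 10.0, seed=3)
        lo, hi = BAND_RANGES[band]
        in_band = dft_band_power_oracle(seg, BandDefinition(band, lo, hi, "suppress"))
        total = dft_band_power_oracle(
            seg, BandDefinition("all", 1e-9, 126.0, "suppress")
        )
        assert np.all(in_band / total >= 0.90)

    def test_amplitude_scaling_squares_band_power(self):
        base = make_painfree_profile(0, pink_noise_scale=0.0, artifact_rate=0.0)
        scaled = make_painfree_profile(
            0,
            band_amplitudes={b: 3.0 * a for b, a in base.band_amplitudes.items()},
            pink_noise_scale=0.0,
            artifact_rate=0.0,
        )
        theta = BandDefinition("theta", 4.0, 7.0, "suppress")
        p1 = dft_band_power_oracle(generate_segment(base, 4.0, seed=8), theta)
        p9 = dft_band_power_oracle(generate_segment(scaled, 4.0, seed=8), theta)
        assert np.allclose(p9 / p1, 9.0, rtol=1e-6)

    def test_noise_scaling_squares_total_power_within_mc_tolerance(self):
        base = make_painfree_profile(0, artifact_rate=0.0)
        scaled = make_painfree_profile(
            0,
            band_amplitudes={
                b: 2.0 * a for b, a in base.band_amplitudes.items()
            },
            pink_noise_scale=2.0 * base.pink_noise_scale,
            artifact_rate=0.0,
        )
        s1 = generate_segment(base, 30.0, seed=11)
        s2 = generate_segment(scaled, 30.0, seed=11)
        ratio = np.mean(s2.data**2) / np.mean(s1.data**2)
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_expected_band_power_tracks_realised_power(self):
        model = make_pain_profile(0, artifact_rate=0.0)
        theta = BandDefinition("theta", 4.0, 7.0, "suppress")
        realised = np.mean(
            [
                dft_band_power_oracle(
                    generate_segment(model, 30.0, seed=s), theta
                ).mean()
                for s in range(10)
            ]
        )
        assert realised == pytest.approx(
            expected_band_power(model, 4.0, 7.0), rel=0.1
        )


class TestLearner:
    def test_zero_responsiveness_is_inert(self):
        m = make_pain_profile(0, responsiveness=0.0)
        assert step_learner(m, _decision(True)) is m
        assert step_learner(m, _decision(False)) is m

    def test_sustained_success_moves_amplitudes_in_trained_directions(self):
        m = make_pain_profile(0, responsiveness=1.0)
        start = dict(m.band_amplitudes)
        for _ in range(100):
            m = step_learner(m, _decision(True))
        for band in REINFORCED_BANDS:  # SMR constituents strictly up
            assert m.band_amplitudes[band] > start[band]
        for band in SUPPRESSED_BANDS:
            assert m.band_amplitudes[band] < start[band]
        assert m.skill > 0

    def test_failures_relax_toward_trait(self):
        m = make_pain_profile(0, responsiveness=1.0)
        for _ in range(50):
            m = step_learner(m, _decision(True))
        drifted = m.band_amplitudes["theta"]
        for _ in range(500):
            m = step_learner(m, _decision(False))
        trait = m.trait_amplitudes["theta"]
        assert abs(m.band_amplitudes["theta"] - trait) < abs(drifted - trait)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_amplitudes_never_negative_under_any_decision_sequence(self, seq):
        m = make_pain_profile(0, responsiveness=1.0)
        for ok in seq:
            m = step_learner(m, _decision(ok))
            assert all(a >= 0 for a in m.band_amplitudes.values())
            assert 0.0 <= m.skill <= 1.0

    def test_smr_amplitude_nondecreasing_under_positive_feedback(self):
        m = make_pain_profile(0, responsiveness=0.7)
        prev = m.band_amplitudes["high_alpha"]
        for _ in range(300):
            m = step_learner(m, _decision(True))
            assert m.band_amplitudes["high_alpha"] >= prev
            prev = m.band_amplitudes["high_alpha"]

    def test_relax_model_approaches_trait_and_keeps_skill(self):
        m = make_pain_profile(0, responsiveness=1.0)
        for _ in range(100):
            m = step_learner(m, _decision(True))
        relaxed = relax_model(m, duration=1e6)
        for band, trait in m.trait_amplitudes.items():
            assert relaxed.band_amplitudes[band] == pytest.approx(trait)
        assert relaxed.skill == m.skill
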