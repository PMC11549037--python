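"""Band-power estimation: Welch vs DFT oracle, Parseval, band membership."""

import numpy as np
import pytest

from neurofb import (
    BandDefinition,
    BandScheme,
    default_scheme,
    dft_band_power_oracle,
    resting_spectrum_report,
    welch_band_powers,
)
from neurofb.synthsig import (
    generate_segment,
    make_pain_profile,
    make_painfree_profile,
)

from conftest import FS, sinusoid_segment


class TestSchemeValidation:
    def test_default_scheme_bands_and_directions(self, scheme):
        assert scheme.names == ("theta", "smr", "high_beta")
        by_name = {b.name: b for b in scheme}
        assert (by_name["theta"].f_low, by_name["theta"].f_high) == (4.0, 7.0)
        assert (by_name["smr"].f_low, by_name["smr"].f_high) == (10.0, 15.0)
        assert (by_name["high_beta"].f_low, by_name["high_beta"].f_high) == (20.0, 30.0)
        assert by_name["theta"].direction == "suppress"
        assert by_name["smr"].direction == "reinforce"
        assert by_name["high_beta"].direction == "suppress"

    def test_scheme_rejects_wrong_count_and_overlap(self):
        b = BandDefinition("theta", 4, 7, "suppress")
        with pytest.raises(ValueError, match="three"):
            BandScheme(bands=(b,))
        with pytest.raises(ValueError, match="overlap"):
            BandScheme(
                bands=(
                    b,
                    BandDefinition("x", 6, 12, "reinforce"),
                    BandDefinition("y", 20, 30, "suppress"),
                )
            )

    def test_band_rejects_bad_edges(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 7, 4, "suppress")
        with pytest.raises(ValueError):
            BandDefinition("bad", 4, 7, "sideways")


class TestOracle:
    def test_zero_signal_gives_zero(self, scheme):
        seg = sinusoid_segment([])
        for band in scheme:
            assert np.all(dft_band_power_oracle(seg, band) == 0.0)

    def test_unit_6hz_sinusoid_theta_power_is_half(self, scheme):
        # A=1 peak → power A²/2 = 0.5
        seg = sinusoid_segment([(6.0, 1.0)], duration=2.0)
        theta = dft_band_power_oracle(seg, scheme.bands[0])
        assert theta == pytest.approx(0.5, rel=1e-6)

    def test_parseval_partition_recovers_total_power(self):
        rng = np.random.default_rng(7)
        seg_data = rng.standard_normal((2, 500))
        from neurofb import EegSegment

        seg = EegSegment(("C3", "C4"), FS, seg_data)
        edges = [0.0, 4.0, 7.0, 10.0, 15.0, 20.0, 30.0, FS / 2 + 1.0]
        total = sum(
            dft_band_power_oracle(seg, BandDefinition(f"b{i}", lo, hi, "suppress"))
            for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
            if lo > 0
        )
        # add the DC..4 Hz part with a tiny positive lower edge
        total = total + dft_band_power_oracle(
            seg, BandDefinition("lowest", 1e-9, 4.0, "suppress")
        )
        ms = np.mean(
            (seg_data - seg_data.mean(axis=-1, keepdims=True)) ** 2, axis=-1
        )
        assert np.allclose(total, ms, rtol=1e-9)


class TestWelch:
    def test_zero_segment_all_bands_zero(self, scheme):
        bp = welch_band_powers(sinusoid_segment([]), scheme, window=1.0)
        assert np.all(bp.powers == 0.0)

    def test_12hz_sinusoid_lands_in_smr_with_correct_total(self, scheme):
        amp = 3.0
        seg = sinusoid_segment([(12.0, amp)], duration=2.0)
        bp = welch_band_powers(seg, scheme, window=2.0, overlap=0.0)
        total = dft_band_power_oracle(
            seg, BandDefinition("all", 1e-9, FS / 2 + 1, "suppress")
        )[0]
        assert bp.band("smr")[0] / total >= 0.9
        assert total == pytest.approx(amp**2 / 2, rel=0.05)

    def test_6hz_sinusoid_theta_dominates(self, scheme):
        bp = welch_band_powers(
            sinusoid_segment([(6.0, 1.0)]), scheme, window=2.0, overlap=0.0
        )
        per_band = bp.channel_mean()
        assert per_band[0] > per_band[1] and per_band[0] > per_band[2]

    def test_matches_oracle_on_multisinusoid(self, scheme):
        # bin-centred frequencies (duration 2 s → 0.5 Hz grid), one per band
        seg = sinusoid_segment(
            [(6.0, 1.0), (12.5, 2.0), (25.0, 0.7)], duration=2.0
        )
        bp = welch_band_powers(seg, scheme, window=2.0, overlap=0.0)
        for j, band in enumerate(scheme):
            oracle = dft_band_power_oracle(seg, band)
            assert np.allclose(bp.powers[:, j], oracle, rtol=1e-6)

    def test_power_scales_quadratically(self, scheme):
        seg1 = sinusoid_segment([(6.0, 1.0), (12.5, 1.0)])
        seg3 = sinusoid_segment([(6.0, 3.0), (12.5, 3.0)])
        bp1 = welch_band_powers(seg1, scheme, window=2.0, overlap=0.0)
        bp3 = welch_band_powers(seg3, scheme, window=2.0, overlap=0.0)
        nz = bp1.powers > 1e-12
        assert np.allclose(bp3.powers[nz] / bp1.powers[nz], 9.0, rtol=1e-9)

    @pytest.mark.parametrize(
        "freq,winner", [(6.9, "theta"), (7.1, None), (14.9, "smr"), (19.9, None)]
    )
    def test_band_edges_are_half_open(self, scheme, freq, winner):
        # 20 s epoch → 0.05 Hz resolution; dominant power must fall on the
        # correct side of the band edge
        seg = sinusoid_segment([(freq, 1.0)], duration=20.0)
        bp = welch_band_powers(seg, scheme, window=20.0, overlap=0.0)
        per_band = dict(zip(bp.band_names, bp.channel_mean()))
        in_bands = sum(per_band.values())
        if winner is None:
            assert in_bands < 0.25  # most power outside every targeted band
        else:
            assert per_band[winner] / 0.5 > 0.75

    def test_nonnegative_and_finite_on_noise(self, scheme):
        seg = generate_segment(make_pain_profile(0), 4.0, seed=9)
        bp = welch_band_powers(seg, scheme, window=1.0, overlap=0.5)
        assert np.all(np.isfinite(bp.powers)) and np.all(bp.powers >= 0)

    def test_short_segment_error_names_minimum(self, scheme):
        seg = sinusoid_segment([(6.0, 1.0)], duration=0.5)
        with pytest.raises(ValueError, match="shorter than"):
            welch_band_powers(seg, scheme, window=1.0)

    def test_invalid_overlap_rejected(self, scheme):
        seg = sinusoid_segment([(6.0, 1.0)])
        with pytest.raises(ValueError, match="overlap"):
            welch_band_powers(seg, scheme, window=1.0, overlap=1.0)


class TestRestingReport:
    def test_relative_powers_sum_below_one(self, scheme):
        seg = generate_segment(make_painfree_profile(2), 120.0, seed=2)
        rep = resting_spectrum_report(seg, scheme)
        assert np.all(rep.relative.sum(axis=1) <= 1.0 + 1e-9)
        assert rep.n_epochs_used >= 10

    def test_deterministic_for_identical_input(self, scheme):
        seg = generate_segment(make_painfree_profile(3), 90.0, seed=3)
        r1 = resting_spectrum_report(seg, scheme)
        r2 = resting_spectrum_report(seg, scheme)
        assert np.array_equal(r1.absolute, r2.absolute)
        assert np.array_equal(r1.relative, r2.relative)

    def test_pain_profile_has_higher_relative_theta(self, scheme):
        # averaged over 20 seeds, the pain profile's theta share exceeds
        # the pain-free profile's
        diffs = []
        for seed in range(20):
            pain = resting_spectrum_report(
                generate_segment(make_pain_profile(seed), 120.0, seed=seed), scheme
            )
            free = resting_spectrum_report(
                generate_segment(make_painfree_profile(seed), 120.0, seed=seed),
                scheme,
            )
            diffs.append(pain.relative[:, 0].mean() - free.relative[:, 0].mean())
        assert np.mean(diffs) > 0

    def test_short_recording_rejected(self, scheme):
        seg = generate_segment(make_painfree_profile(1), 30.0, seed=1)
        with pytest.raises(ValueError, match="60"):
            resting_spectrum_report(seg, scheme)
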