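import numpy as np
import pytest

from adaptref.filters import FilterConfig, filter_record
from adaptref.spectral import magnitude_spectrum
from adaptref.synthetic import (
    Component,
    SyntheticSpec,
    gen_gait_epochs,
    gen_record,
    gen_ssvep,
)


class TestGenRecord:
    def test_same_seed_bit_identical(self, occipital):
        r1, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=5)
        r2, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=5)
        assert np.array_equal(r1.data, r2.data)

    def test_different_seed_differs(self, occipital):
        r1, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=5)
        r2, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=6)
        assert not np.array_equal(r1.data, r2.data)

    def test_adding_component_preserves_other_streams(self):
        chans = ["Oz", "O1"]
        base = SyntheticSpec(channels=chans, components=[
            Component("pink_noise", 2.0, gains=1.0)], noise_sigma=1.0, seed=9)
        extended = SyntheticSpec(channels=chans, components=[
            Component("pink_noise", 2.0, gains=1.0),
            Component("sine", 1.0, freq=10.0, gains={"Oz": 1.0})],
            noise_sigma=1.0, seed=9)
        r1, _ = gen_record(base)
        r2, _ = gen_record(extended)
        t = np.arange(r1.n_samples) / r1.fs
        tone = np.sin(2 * np.pi * 10 * t)
        assert r2.channel("O1") == pytest.approx(r1.channel("O1"))
        assert r2.channel("Oz") - tone == pytest.approx(r1.channel("Oz"))

    def test_localized_component_only_on_its_channel(self):
        # 5 s at 250 Hz fills the 0.2 Hz grid exactly: no leakage sidelobes
        spec = SyntheticSpec(
            channels=["Oz", "O1", "O2"], fs=250.0, duration_s=5.0,
            components=[Component("sine", 2.0, freq=12.0, gains={"Oz": 1.0})],
            noise_sigma=0.0, seed=0,
        )
        rec, _ = gen_record(spec)
        fr, m_oz = magnitude_spectrum(rec.channel("Oz"), rec.fs)
        _, m_o1 = magnitude_spectrum(rec.channel("O1"), rec.fs)
        i12 = int(np.argmin(np.abs(fr - 12.0)))
        assert m_oz[i12] > 100 * (np.delete(m_oz, i12).max() + 1e-12)
        assert np.all(m_o1 < 1e-9)

    def test_power_decomposition(self):
        comps = [
            Component("sine", 3.0, freq=11.0, gains=1.0),
            Component("pink_noise", 2.0, gains=1.0),
        ]
        spec = SyntheticSpec(channels=["Oz"], fs=250.0, duration_s=120.0,
                             components=comps, noise_sigma=1.5, seed=1)
        rec, _ = gen_record(spec)
        expected = 3.0**2 / 2 + 2.0**2 + 1.5**2
        measured = float(np.mean(rec.channel("Oz") ** 2))
        assert measured == pytest.approx(expected, rel=0.05)

    def test_too_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            SyntheticSpec(channels=["Oz"], fs=20.0,
                          components=[Component("sine", 1.0, freq=12.0)])


class TestGenSsvep:
    def test_common_tone_suppressed_by_adaptive_filter(self, occipital):
        rec, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=2)
        filt, _ = filter_record(rec.data, rec.channels, rec.fs, occipital,
                                ["Oz"], FilterConfig(mode="ad_war"))
        n = FilterConfig().window_samples(rec.fs)
        fr, m_in = magnitude_spectrum(rec.channel("Oz")[n:], rec.fs)
        _, m_out = magnitude_spectrum(filt["Oz"][n:], rec.fs)
        i50 = int(np.argmin(np.abs(fr - 50.0)))
        # >= 20 dB power reduction of the common line tone
        assert 20 * np.log10(m_out[i50] / m_in[i50]) < -20.0

    def test_snr_monotone_in_local_amplitude(self, occipital):
        from adaptref.spectral import ssvep_snr

        snrs = []
        for amp in (0.5, 2.0, 8.0):
            rec, _ = gen_ssvep(12.0, channels=occipital.electrodes,
                               ssvep_amplitude=amp, seed=3)
            filt, _ = filter_record(rec.data, rec.channels, rec.fs, occipital,
                                    ["Oz"], FilterConfig(mode="ad_war"))
            fr, mag = magnitude_spectrum(filt["Oz"], rec.fs)
            snrs.append(ssvep_snr(fr, mag, 12.0))
        assert snrs[0] < snrs[1] < snrs[2]


class TestGenGaitEpochs:
    def test_session_bookkeeping(self, gait_montage):
        epochs, truth = gen_gait_epochs(channels=gait_montage.electrodes, seed=0)
        assert len(epochs) == 60
        sessions = {}
        for ep in epochs:
            sessions.setdefault(ep.session, []).append(ep.label)
        assert set(sessions) == set(range(6))
        for labels in sessions.values():
            assert len(labels) == 10
            assert sum(labels) == 4  # 4 planning + 6 rest per session

    def test_epoch_durations(self, gait_montage):
        epochs, truth = gen_gait_epochs(channels=gait_montage.electrodes, seed=0)
        for ep in epochs:
            expect = 1.5 if ep.label == 1 else 2.0
            assert ep.record.n_samples == int(expect * truth.fs)

    def test_null_classes_share_slow_component_statistics(self, gait_montage):
        # zero effect sizes: per-class mean low-frequency power must agree
        from adaptref.features import band_power

        epochs, truth = gen_gait_epochs(
            channels=gait_montage.electrodes, seed=1,
            mrcp_amplitude=0.0, mu_erd=0.0,
        )
        czi = gait_montage.index("Cz")
        bp = {0: [], 1: []}
        for ep in epochs:
            bp[ep.label].append(
                band_power(ep.record.data[czi], truth.fs, (0.1, 4.0))
            )
        m0, m1 = np.mean(bp[0]), np.mean(bp[1])
        pooled = np.std(bp[0] + bp[1]) + 1e-12
        assert abs(m0 - m1) / pooled < 0.8

    def test_planted_effect_visible_in_mrcp_band(self, gait_montage):
        # the slow planning ramp shows in the 0.1-4 Hz band of the
        # spatially filtered target (common drift/EOG would mask it raw)
        from adaptref.features import band_power
        from scipy import stats

        epochs, truth = gen_gait_epochs(channels=gait_montage.electrodes, seed=1)
        bp = {0: [], 1: []}
        for ep in epochs:
            filt, _ = filter_record(ep.record.data, ep.record.channels,
                                    truth.fs, gait_montage, ["Cz"],
                                    FilterConfig(mode="ad_war"))
            bp[ep.label].append(band_power(filt["Cz"], truth.fs, (0.1, 4.0)))
        t, p = stats.ttest_ind(bp[1], bp[0], equal_var=False)
        assert p < 0.01 and t > 0

    def test_mu_suppression_during_planning(self, gait_montage):
        from adaptref.features import band_power

        epochs, truth = gen_gait_epochs(channels=gait_montage.electrodes, seed=2)
        czi = gait_montage.index("Cz")
        mu = {0: [], 1: []}
        for ep in epochs:
            mu[ep.label].append(
                band_power(ep.record.data[czi], truth.fs, (8.0, 12.0))
            )
        assert np.mean(mu[1]) < np.mean(mu[0])
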