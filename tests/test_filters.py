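import numpy as np
import pytest

from adaptref.filters import (
    AdaptiveFilter,
    FilterConfig,
    amplitude_correction,
    baseline_weights,
    filter_record,
    virtual_distance,
    weights_from_ccc,
)


@pytest.fixture()
def ad_war():
    return FilterConfig(mode="ad_war")


class TestVirtualDistance:
    def test_closed_form_points(self):
        assert virtual_distance(0.0, 5.0) == pytest.approx(1.0)
        assert virtual_distance(1.0, 5.0) == pytest.approx(np.exp(-5))
        assert virtual_distance(-1.0, 5.0) == pytest.approx(np.exp(5))

    def test_strictly_decreasing(self):
        rho = np.linspace(-1, 1, 50)
        vd = virtual_distance(rho, 5.0)
        assert np.all(np.diff(vd) < 0)

    def test_weights_monotone_in_dissimilarity(self, rng):
        rho = rng.uniform(-1, 1, 8)
        w = weights_from_ccc(rho, 5.0)
        assert w.sum() == pytest.approx(1.0)
        order = np.argsort(rho)
        assert np.all(np.diff(w[order]) <= 0)  # lower rho -> higher weight

    def test_weights_stable_at_extreme_w1(self):
        w = weights_from_ccc(np.array([-1.0, 1.0]), 100.0)
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


class TestBaselineWeights:
    def test_two_equidistant_neighbors(self, occipital):
        nbrs, w = baseline_weights(occipital, "Oz", "lar_small", unit_distances=True)
        assert w == pytest.approx(np.full(len(nbrs), 1 / len(nbrs)))

    def test_inverse_distance_ratio(self):
        from adaptref.montage import ElectrodeMontage

        m = ElectrodeMontage(
            electrodes=["T", "A", "B"],
            positions={"T": np.zeros(3), "A": np.array([1.0, 0, 0]),
                       "B": np.array([2.0, 0, 0])},
            neighbors_small={"T": ["A", "B"]},
        )
        _, w = baseline_weights(m, "T", "lar_small")
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_coincident_electrodes_rejected(self):
        from adaptref.montage import ElectrodeMontage

        m = ElectrodeMontage(
            electrodes=["T", "A"],
            positions={"T": np.zeros(3), "A": np.zeros(3)},
        )
        with pytest.raises(ValueError, match="zero distance"):
            baseline_weights(m, "T", "war")


class TestAmplitudeCorrection:
    def test_quiet_sample_all_zero(self, rng):
        win = rng.standard_normal((3, 25))
        ac = amplitude_correction(win[:, -1], win, [0, 1, 2], vstd_ss=1.0, vstd_th=5.0)
        assert np.all(ac == 0)

    def test_uncorrelated_members_use_global_median(self, rng):
        # three mutually uncorrelated windows -> branch 1: median over SS
        win = rng.standard_normal((3, 50))
        vals = np.array([1.0, 2.0, 9.0])
        ac = amplitude_correction(vals, win, [0, 1, 2], vstd_ss=10.0, vstd_th=1.0)
        assert ac == pytest.approx([2.0, 2.0, 2.0])

    def test_correlated_subgroup_uses_its_own_median(self, rng):
        t = np.linspace(0, 1, 50)
        a = t
        b = t + rng.standard_normal(50) * 1e-3   # r(a, b) ~ 1
        c = rng.standard_normal(50)              # uncorrelated with both
        win = np.vstack([a, b, c])
        vals = np.array([1.0, 5.0, 100.0])
        ac = amplitude_correction(vals, win, [0, 1, 2], vstd_ss=10.0, vstd_th=1.0)
        # a and b form Se = {a, b}: median of {1, 5} = 3
        assert ac[0] == pytest.approx(3.0)
        assert ac[1] == pytest.approx(3.0)
        # c sees min pairwise r < cut -> global median
        assert ac[2] == pytest.approx(5.0)

    def test_singleton_ss_left_alone(self, rng):
        win = rng.standard_normal((2, 25))
        ac = amplitude_correction(win[:, -1], win, [0], vstd_ss=50.0, vstd_th=1.0)
        assert np.all(ac == 0)


class TestFilterRecord:
    def test_common_mode_rejected_exactly(self, occipital, rng, ad_war):
        wave = rng.standard_normal(600) * 30
        data = np.tile(wave, (len(occipital.electrodes), 1))
        filt, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                                config=ad_war)
        n = ad_war.window_samples(250.0)
        for t in occipital.targets:
            assert np.abs(filt[t][n:]).max() < 1e-10

    def test_zero_record_zero_output(self, occipital, ad_war):
        data = np.zeros((len(occipital.electrodes), 200))
        filt, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                                config=ad_war)
        assert np.all(filt["Oz"] == 0)

    def test_uniform_similarity_equals_unit_distance_baseline(
        self, occipital, rng
    ):
        # all neighbors carry the identical signal -> equal ccc -> uniform g
        C = len(occipital.electrodes)
        sig, nb = rng.standard_normal(500) * 10, rng.standard_normal(500) * 10
        data = np.tile(nb, (C, 1))
        data[occipital.index("Oz")] = sig
        for ad_mode, base_mode in (("ad_war", "war"), ("ad_lar_small", "lar_small")):
            f_ad, _ = filter_record(
                data, occipital.electrodes, 250.0, occipital, ["Oz"],
                FilterConfig(mode=ad_mode),
            )
            f_bl, _ = filter_record(
                data, occipital.electrodes, 250.0, occipital, ["Oz"],
                FilterConfig(mode=base_mode, unit_distances=True),
            )
            n = FilterConfig().window_samples(250.0)
            assert np.abs(f_ad["Oz"][n:] - f_bl["Oz"][n:]).max() < 1e-10

    def test_batch_equals_streaming(self, occipital, rng, ad_war):
        C = len(occipital.electrodes)
        data = rng.standard_normal((C, 250)) * 10
        data[2, 120:160] += 150  # force engaged samples and corrections
        batch, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                                 config=ad_war)
        af = AdaptiveFilter(occipital, config=ad_war, fs=250.0)
        for k in range(data.shape[1]):
            out = af.step(data[:, k])
            for t in occipital.targets:
                assert out[t].value == pytest.approx(batch[t][k], abs=1e-9)

    def test_causality(self, occipital, rng, ad_war):
        C = len(occipital.electrodes)
        data = rng.standard_normal((C, 300)) * 10
        f1, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                              ["Oz"], ad_war)
        data2 = data.copy()
        data2[:, 200:] += rng.standard_normal((C, 100)) * 40
        f2, _ = filter_record(data2, occipital.electrodes, 250.0, occipital,
                              ["Oz"], ad_war)
        assert f1["Oz"][:200] == pytest.approx(f2["Oz"][:200], abs=0)

    def test_determinism(self, occipital, rng, ad_war):
        data = rng.standard_normal((len(occipital.electrodes), 400)) * 10
        f1, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                              ["Oz"], ad_war)
        f2, _ = filter_record(data, occipital.electrodes, 250.0, occipital,
                              ["Oz"], ad_war)
        assert np.array_equal(f1["Oz"], f2["Oz"])

    def test_weights_sum_to_one_every_sample(self, occipital, rng, ad_war):
        C = len(occipital.electrodes)
        data = rng.standard_normal((C, 400)) * 10
        data[5, 200:230] += 200
        _, diags = filter_record(data, occipital.electrodes, 250.0, occipital,
                                 ["Oz"], ad_war)
        d = diags["Oz"]
        post = ~d.warmup
        sums = d.weights[:, post].sum(axis=0)
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-9)

    def test_warmup_policies(self, occipital, rng):
        C = len(occipital.electrodes)
        data = rng.standard_normal((C, 60)) * 10
        n = FilterConfig().window_samples(250.0)
        f_pass, _ = filter_record(
            data, occipital.electrodes, 250.0, occipital, ["Oz"],
            FilterConfig(mode="ad_war", warmup_policy="passthrough"),
        )
        ozi = occipital.index("Oz")
        assert f_pass["Oz"][: n - 1] == pytest.approx(data[ozi, : n - 1])
        f_base, _ = filter_record(
            data, occipital.electrodes, 250.0, occipital, ["Oz"],
            FilterConfig(mode="ad_war", warmup_policy="baseline_weights"),
        )
        f_war, _ = filter_record(
            data, occipital.electrodes, 250.0, occipital, ["Oz"],
            FilterConfig(mode="war"),
        )
        assert f_base["Oz"][: n - 1] == pytest.approx(f_war["Oz"][: n - 1])

    def test_channel_mismatch_rejected(self, occipital, rng, ad_war):
        data = rng.standard_normal((3, 100))
        with pytest.raises(KeyError):
            filter_record(data, ["Oz", "O1", "O2"], 250.0, occipital,
                          ["Oz", "PO3"], ad_war)
        af = AdaptiveFilter(occipital, config=ad_war, fs=250.0)
        with pytest.raises(ValueError, match="channel"):
            af.step(np.zeros(3))

    def test_case_insensitive_channel_match(self, occipital, rng, ad_war):
        labels = [c.upper() for c in occipital.electrodes]
        data = rng.standard_normal((len(labels), 120))
        filt, _ = filter_record(data, labels, 250.0, occipital, ["Oz"], ad_war)
        assert "Oz" in filt


def test_localized_component_better_preserved_than_war(occipital):
    """Target-localized oscillation survives Ad WAR better than WAR."""
    from adaptref.spectral import attenuation, magnitude_spectrum
    from adaptref.synthetic import gen_ssvep

    wins = 0
    for seed in range(6):
        rec, _ = gen_ssvep(12.0, channels=occipital.electrodes, seed=seed)
        fr, mag_in = magnitude_spectrum(rec.channel("Oz"), rec.fs)
        atts = {}
        for mode in ("war", "ad_war"):
            filt, _ = filter_record(rec.data, rec.channels, rec.fs, occipital,
                                    ["Oz"], FilterConfig(mode=mode))
            _, mag_out = magnitude_spectrum(filt["Oz"], rec.fs)
            atts[mode] = attenuation(fr, mag_in, mag_out, 12.0)
        wins += abs(atts["ad_war"]) <= abs(atts["war"])
    assert wins >= 5
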