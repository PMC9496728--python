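"""PLV, envelope phase, splicing, shuffle nulls, profiles and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tgpac as tg
from tgpac.pac import splice_indices

from conftest import coupling_phases, single_channel_recording


class TestPLVSingleTrial:
    def test_constant_difference_is_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, 200)
        assert tg.plv_single_trial(th, th - 1.3) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_pair_is_zero(self):
        assert tg.plv_single_trial(np.array([0.0, np.pi]), np.zeros(2)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_chance_level_matches_rayleigh_oracle(self, rng):
        # E[PLV] for N iid uniform differences ~ sqrt(pi)/(2 sqrt(N))
        n, reps = 740, 2000
        vals = [
            tg.plv_single_trial(rng.uniform(0, 2 * np.pi, n), np.zeros(n))
            for _ in range(reps)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(n)), rel=0.05)

    def test_errors(self):
        with pytest.raises(ValueError):
            tg.plv_single_trial(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            tg.plv_single_trial(np.zeros(1), np.zeros(1))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        phases=arrays(float, st.integers(2, 60),
                      elements=st.floats(-np.pi, np.pi)),
        rot=st.floats(-10, 10),
    )
    def test_bounded_and_rotation_invariant(self, phases, rot):
        ref = np.linspace(-3, 3, phases.size)
        v = tg.plv_single_trial(phases, ref)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert tg.plv_single_trial(phases + rot, ref) == pytest.approx(v, abs=1e-9)


class TestEnvelopePhase:
    def test_cosine_envelope_has_zero_phase_at_maxima(self):
        fs, f = 500.0, 6.0
        t = np.arange(int(2 * fs)) / fs
        env = 1.0 + 0.5 * np.cos(2 * np.pi * f * t)
        phase = tg.envelope_phase(env[None, :])[0]
        interior = slice(100, -100)
        peaks = [i for i in range(*interior.indices(t.size))
                 if env[i] >= env[i - 1] and env[i] >= env[i + 1]]
        for i in peaks:
            assert abs(phase[i]) < 2 * np.pi * f / fs + 0.02

    def test_invariant_to_affine_rescaling(self, rng):
        env = 2.0 + rng.random(400)
        a = tg.envelope_phase(env)
        b = tg.envelope_phase(3.0 * env + 5.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_flat_envelope_flagged_as_undefined(self):
        phase = tg.envelope_phase(np.full((2, 100), 3.0))
        assert np.isnan(phase).all()

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            tg.envelope_phase(np.array([-1.0, 1.0, 2.0]))


class TestSplice:
    def test_equal_target_is_a_permutation(self, rng):
        th = rng.uniform(size=50)
        ep = rng.uniform(size=50)
        th2, ep2 = tg.splice_to_length(th, ep, 50, rng)
        assert sorted(th2) == sorted(th)
        # pairing intact: every output pair exists in the input
        pairs = set(zip(th.round(12), ep.round(12)))
        assert set(zip(th2.round(12), ep2.round(12))) <= pairs

    def test_pre_window_splices_to_post_length(self, rng):
        # 740 pre-stimulus samples at 1000 Hz resampled to the 1600-sample
        # post window
        times = -1500.0 + np.arange(4000)
        n_pre = tg.PRE_WINDOW.n_samples(times)
        n_post = tg.POST_WINDOW.n_samples(times)
        assert (n_pre, n_post) == (740, 1600)
        th = rng.uniform(size=n_pre)
        th2, _ = tg.splice_to_length(th, th.copy(), n_post, rng)
        assert th2.size == 1600

    def test_constant_difference_survives_splicing(self, rng):
        th = rng.uniform(0, 2 * np.pi, 100)
        th2, ep2 = tg.splice_to_length(th, th - 0.8, 777, rng)
        assert tg.plv_single_trial(th2, ep2) == pytest.approx(1.0, abs=1e-12)

    def test_short_target_warns_and_returns_input(self, rng):
        th = np.arange(10.0)
        with pytest.warns(UserWarning, match="unchanged"):
            th2, ep2 = tg.splice_to_length(th, th, 5, rng)
        np.testing.assert_array_equal(th2, th)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(n=st.integers(2, 40), extra=st.integers(0, 90), seed=st.integers(0, 99))
    def test_multiplicities_differ_by_at_most_one_per_block(self, n, extra, seed):
        idx = splice_indices(n, n + extra, np.random.default_rng(seed))
        counts = np.bincount(idx, minlength=n)
        assert idx.size == n + extra
        assert counts.max() - counts.min() <= 1


class TestWindowedPLV:
    def test_identical_trials_average_to_single_trial_value(self):
        rec = single_channel_recording(m=0.7, seed=3, n_trials=1, noise_amp=0.0)
        data = np.repeat(rec.data, 5, axis=1)
        rec5 = rec.copy_with(data, conditions=np.array(["c"] * 5))
        th, amp, gf = coupling_phases(rec5)
        tab = tg.windowed_plv(th, amp, tg.POST_WINDOW, times=rec5.times,
                              conditions=rec5.conditions, ch_names=rec5.ch_names,
                              gamma_freqs=gf)
        th1, amp1, _ = coupling_phases(rec)
        tab1 = tg.windowed_plv(th1, amp1, tg.POST_WINDOW, times=rec.times,
                               conditions=rec.conditions, ch_names=rec.ch_names,
                               gamma_freqs=gf)
        np.testing.assert_allclose(tab.plv.to_numpy(), tab1.plv.to_numpy(),
                                   atol=1e-12)
        assert (tab.n_trials == 5).all()

    def test_global_theta_rotation_leaves_plv_unchanged(self):
        rec = single_channel_recording(m=0.5, seed=4, n_trials=6)
        th, amp, gf = coupling_phases(rec)
        kw = dict(times=rec.times, conditions=rec.conditions,
                  ch_names=rec.ch_names, gamma_freqs=gf)
        a = tg.windowed_plv(th, amp, tg.POST_WINDOW, **kw)
        rotated = np.angle(np.exp(1j * (th + 1.234)))
        b = tg.windowed_plv(rotated, amp, tg.POST_WINDOW, **kw)
        np.testing.assert_allclose(a.plv.to_numpy(), b.plv.to_numpy(), atol=1e-9)

    def test_plv_within_unit_interval_and_monotone_in_depth(self):
        values = []
        for m in (0.0, 0.5, 1.0):
            rec = single_channel_recording(m=m, seed=11, n_trials=20)
            th, amp, gf = coupling_phases(rec)
            tab = tg.windowed_plv(th, amp, tg.POST_WINDOW, times=rec.times,
                                  conditions=rec.conditions,
                                  ch_names=rec.ch_names, gamma_freqs=gf)
            v = tab.plv.iloc[0]
            assert 0.0 <= v <= 1.0
            values.append(v)
        assert values[0] < values[1] < values[2]


class TestShuffleNull:
    def test_noiseless_coupling_separates_completely_from_null(self):
        rec = single_channel_recording(m=0.8, seed=5, n_trials=8, noise_amp=0.0)
        th, amp, gf = coupling_phases(rec)
        kw = dict(times=rec.times, conditions=rec.conditions,
                  ch_names=rec.ch_names, gamma_freqs=gf)
        obs = tg.windowed_plv(th, amp, tg.POST_WINDOW, **kw).plv.iloc[0]
        null = tg.shuffle_null(th, amp, tg.POST_WINDOW, 100,
                               rng=np.random.default_rng(0), **kw)
        assert (null.table.plv < obs).all()

    def test_timepoint_shuffle_matches_rayleigh_chance(self):
        rec = single_channel_recording(m=0.0, seed=6, n_trials=20)
        th, amp, gf = coupling_phases(rec)
        null = tg.shuffle_null(th, amp, tg.POST_WINDOW, 60,
                               method="timepoint_shuffle",
                               rng=np.random.default_rng(1),
                               times=rec.times, conditions=rec.conditions,
                               ch_names=rec.ch_names, gamma_freqs=gf)
        n = tg.POST_WINDOW.n_samples(rec.times)
        # trial-averaged over 20 trials: mean of the null sits near the
        # single-trial Rayleigh mean for N iid samples
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert null.table.plv.mean() == pytest.approx(expected, rel=0.15)

    def test_unknown_method_rejected(self):
        rec = single_channel_recording(m=0.0, seed=1, n_trials=3)
        th, amp, gf = coupling_phases(rec)
        with pytest.raises(ValueError, match="method"):
            tg.shuffle_null(th, amp, tg.POST_WINDOW, 10, method="bogus",
                            times=rec.times, conditions=rec.conditions,
                            ch_names=rec.ch_names, gamma_freqs=gf)


class TestAggregate:
    def _table(self, value=0.3):
        rows = []
        for w in ("pre", "post"):
            for ch in ("F1", "F2", "P1"):
                for f in np.arange(25.0, 36.0):
                    rows.append({"condition": "c", "window": w, "channel": ch,
                                 "gamma_freq": f, "plv": value})
        return pd.DataFrame(rows)

    def test_constant_table_aggregates_to_constant(self):
        out = tg.aggregate(self._table(0.3), (25.0, 35.0), ["F1", "F2"])
        assert set(out.columns) >= {"condition", "window", "plv"}
        np.testing.assert_allclose(out.plv, 0.3)

    def test_band_selects_eleven_rows_and_order_invariance(self):
        tab = self._table()
        sel = tab[(tab.gamma_freq >= 25) & (tab.gamma_freq <= 35)]
        assert sel.gamma_freq.nunique() == 11
        a = tg.aggregate(tab, (25.0, 35.0), ["F1", "F2", "P1"])
        b = tg.aggregate(tab, (25.0, 35.0), ["P1", "F1", "F2"])
        pd.testing.assert_frame_equal(
            a.sort_values(["condition", "window"]).reset_index(drop=True),
            b.sort_values(["condition", "window"]).reset_index(drop=True),
        )

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            tg.aggregate(self._table(), (25.0, 35.0), [])


class TestPhaseBinProfile:
    def test_flat_amplitude_gives_flat_unit_profile(self, rng):
        th = rng.uniform(-np.pi, np.pi, (4, 500))
        prof = tg.phase_bin_profile(th, np.full((4, 500), 2.5))
        np.testing.assert_allclose(prof.means[np.isfinite(prof.means)], 1.0)

    def test_cosine_modulation_recovers_shape_and_peak(self, rng):
        phi_c = 0.9
        th = rng.uniform(-np.pi, np.pi, (1, 200_000))
        amp = 1.0 + 0.5 * np.cos(th - phi_c)
        prof = tg.phase_bin_profile(th, amp, n_bins=18)
        # numeric oracle: mean of 1+0.5cos(x-phi_c) over each bin
        edges = prof.bin_edges
        for k in range(18):
            a, b = edges[k], edges[k + 1]
            oracle = 1.0 + 0.5 * (np.sin(b - phi_c) - np.sin(a - phi_c)) / (b - a)
            assert prof.means[k] == pytest.approx(oracle, abs=0.02)
        peak = prof.bin_centers[np.nanargmax(prof.means)]
        width = 2 * np.pi / 18
        assert abs(np.angle(np.exp(1j * (peak - phi_c)))) <= width
        assert tg.preferred_phase(prof) == pytest.approx(phi_c, abs=0.05)

    def test_count_weighted_mean_is_exactly_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, (3, 700))
        amp = rng.random((3, 700)) + 0.5
        prof = tg.phase_bin_profile(th, amp)
        total = np.nansum(prof.means * prof.counts) / prof.counts.sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_bin_is_nan_not_zero(self):
        th = np.full((1, 50), 0.1)  # all phases in one bin
        amp = np.ones((1, 50))
        prof = tg.phase_bin_profile(th, amp)
        assert np.isnan(prof.means).sum() == 17
        assert prof.counts.sum() == 50


class TestClusterPhaseHomogeneity:
    def test_heterogeneous_phases_flatten_cluster_profile_not_plv(self):
        # per-electrode coupling phases drawn uniform leave each electrode's
        # PLV alone but collapse the cluster-averaged phase-amplitude profile
        def cluster_run(spread, seed):
            rng = np.random.default_rng(seed)
            montage = tg.make_montage(1, 8, posterior_phase_spread=spread, rng=rng)
            cfg = tg.SynthConfig(fs=500.0, m=0.8, n_trials=15,
                                 coupling_windows={"pre": 0.0, "post": 0.8},
                                 conditions=("c",), montage=montage, seed=seed)
            rec = tg.generate_epoched_dataset(cfg)
            th, amp, gf = coupling_phases(rec)
            tab = tg.windowed_plv(th, amp, tg.POST_WINDOW, times=rec.times,
                                  conditions=rec.conditions,
                                  ch_names=rec.ch_names, gamma_freqs=gf)
            sl = tg.POST_WINDOW.sample_slice(rec.times)
            profs = [
                tg.phase_bin_profile(th[ci, :, sl], amp[ci, :, 0, sl])
                for ci, ch in enumerate(rec.ch_names) if ch.startswith("P")
            ]
            post = tab[tab.channel.str.startswith("P")]
            return post.plv.mean(), tg.modulation_depth(tg.average_profiles(profs))

        plv_hom, depth_hom = cluster_run(0.0, 21)
        plv_het, depth_het = cluster_run(2 * np.pi, 21)
        assert plv_het == pytest.approx(plv_hom, rel=0.10)
        assert depth_het <= 0.5 * depth_hom
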