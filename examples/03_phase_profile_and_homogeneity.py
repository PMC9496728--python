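"""Phase-binned amplitude profiles and the cluster-homogeneity effect.

The profile of mean normalized gamma amplitude across 18 theta-phase bins
peaks at the preferred coupling phase.  When electrodes in a cluster couple
at *different* preferred phases, averaging their profiles flattens the
cluster curve even though each electrode's PLV is unchanged — the reason a
cluster-average plot can understate coupling that PLV still detects.
"""

import numpy as np

import tgpac as tg


def cluster_profile(phase_spread: float, seed: int = 7):
    rng = np.random.default_rng(seed)
    montage = tg.make_montage(1, 8, posterior_phase_spread=phase_spread, rng=rng)
    cfg = tg.SynthConfig(m=0.8, coupling_windows={"pre": 0.0, "post": 0.8},
                         n_trials=20, conditions=("c",), montage=montage,
                         seed=seed)
    rec = tg.generate_epoched_dataset(cfg)
    dec = tg.morlet_decompose(rec, [6.0, 40.0])
    th = tg.extract_phase(dec, 6.0)
    amp, gf = tg.extract_amplitude(dec, (40.0, 40.0))
    tab = tg.windowed_plv(th, amp, tg.POST_WINDOW, times=rec.times,
                          conditions=rec.conditions, ch_names=rec.ch_names,
                          gamma_freqs=gf)
    sl = tg.POST_WINDOW.sample_slice(rec.times)
    profiles = [
        tg.phase_bin_profile(th[ci, :, sl], amp[ci, :, 0, sl])
        for ci, ch in enumerate(rec.ch_names) if ch.startswith("P")
    ]
    cluster = tg.average_profiles(profiles)
    plv = tab[tab.channel.str.startswith("P")].plv.mean()
    return plv, tg.modulation_depth(cluster)


plv_hom, depth_hom = cluster_profile(0.0)
plv_het, depth_het = cluster_profile(2 * np.pi)

print(f"homogeneous cluster : mean PLV {plv_hom:.3f}, profile depth {depth_hom:.3f}")
print(f"heterogeneous cluster: mean PLV {plv_het:.3f}, profile depth {depth_het:.3f}")
print("\nPLV is phase-agnostic, so it survives per-electrode phase scatter; "
      "the\ncluster-averaged profile depth collapses instead.")
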