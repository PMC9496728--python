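"""Benchmark an observed PLV against its circular-shift permutation null.

Chance-level PLV depends on window length and the autocorrelation of the
envelope, so raw PLV values are not interpretable alone; the shuffle null
provides the reference.  Here the coupled signal (depth 0.6) lands far above
the null's 99th percentile, while an uncoupled signal does not.
"""

import numpy as np

import tgpac as tg


def observed_and_null(m: float, seed: int):
    cfg = tg.SynthConfig(
        m=m, coupling_windows={"pre": 0.0, "post": m},
        n_trials=30, conditions=("c",), montage=tg.make_montage(1, 1),
        seed=seed,
    )
    rec = tg.generate_epoched_dataset(cfg)
    dec = tg.morlet_decompose(rec, [6.0, 40.0])
    th = tg.extract_phase(dec, 6.0)
    amp, gf = tg.extract_amplitude(dec, (40.0, 40.0))
    kw = dict(times=rec.times, conditions=rec.conditions,
              ch_names=rec.ch_names, gamma_freqs=gf)
    obs = tg.windowed_plv(th, amp, tg.POST_WINDOW, **kw).plv.iloc[0]
    null = tg.shuffle_null(th, amp, tg.POST_WINDOW, n_perm=200,
                           rng=np.random.default_rng(seed + 1), **kw)
    return obs, null.table.plv.to_numpy()


for m in (0.6, 0.0):
    obs, null = observed_and_null(m, seed=4)
    q99 = np.percentile(null, 99)
    verdict = "exceeds" if obs > q99 else "does not exceed"
    print(f"depth m={m}: observed PLV {obs:.3f} {verdict} the null 99th "
          f"percentile {q99:.3f} (null mean {null.mean():.3f})")

print("\nOnly genuinely coupled data should beat the null; uncoupled data "
      "stays inside it.")
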