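"""Simulate coupled EEG and measure theta-gamma PLV in both analysis windows.

Generates 30 trials of a single-channel-pair recording in which gamma (40 Hz)
amplitude is modulated by theta (6 Hz) phase only after stimulus onset
(depth 0 before, 0.6 after), then measures the trial-averaged envelope-phase
PLV in the pre-stimulus (-940..-200 ms) and post-stimulus (300..1900 ms)
windows.  The post-window PLV should clearly exceed the pre-window PLV.
"""

import numpy as np

import tgpac as tg

cfg = tg.SynthConfig(
    coupling_windows={"pre": 0.0, "post": 0.6},
    n_trials=30,
    conditions=("ActiveWM+",),
    montage=tg.make_montage(1, 1),
    seed=1,
)
rec = tg.generate_epoched_dataset(cfg)

decomp = tg.morlet_decompose(rec, [6.0, 40.0])
theta_phase = tg.extract_phase(decomp, 6.0)
amplitude, gamma_freqs = tg.extract_amplitude(decomp, (40.0, 40.0))

rng = np.random.default_rng(1)
target = tg.POST_WINDOW.n_samples(rec.times)
for window in (tg.PRE_WINDOW, tg.POST_WINDOW):
    eq = target if window.n_samples(rec.times) < target else None
    tab = tg.windowed_plv(
        theta_phase, amplitude, window,
        times=rec.times, conditions=rec.conditions,
        ch_names=rec.ch_names, gamma_freqs=gamma_freqs,
        equalize_to=eq, rng=rng,
    )
    plv = tab.plv.mean()
    print(f"{window.name:>4}-stimulus window: PLV = {plv:.3f} "
          f"({tab.n_points.iloc[0]} time points/trial)")

print("\nPLV near chance (~0.2-0.3 for these window lengths) before the "
      "stimulus,\nand well above it afterwards, reflects the injected "
      "post-stimulus coupling.")
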