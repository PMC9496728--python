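"""A complete 20-subject in-silico study with the planned statistics.

Simulates the three-task design (change detection, active attention, passive
viewing) with coupling that rises after stimulus onset *equally* in all
conditions, runs the full pipeline per subject, and applies the planned
tests.  The expected pattern: a strong window (pre vs post) effect, but a
null focused working-memory contrast — the signature of coupling that is not
memory-specific.
"""

import tgpac as tg

synth = tg.SynthConfig(
    fs=500.0,
    n_trials=10,
    coupling_windows={"pre": 0.0, "post": 0.4},  # same rise in every task
    montage=tg.make_montage(1, 1),
)
config = tg.StudyConfig(
    synth=synth, behavior=tg.BehavioralConfig(true_K=3.0),
    n_subjects=20, bands={"gamma40": (40.0, 40.0)}, seed=3,
)

result = tg.run_study(config)
cells = result["cells"]

print("mean PLV by window (frontal, 40 Hz):")
front = cells[cells.cluster == "frontal"]
print(front.groupby("window").plv.mean().round(3).to_string(), "\n")

print("planned tests (frontal cluster):")
contrasts = result["contrasts"]
view = contrasts[contrasts.cluster == "frontal"][["effect", "t", "df", "p", "d"]]
print(view.to_string(index=False, float_format=lambda v: f"{v:.3g}"), "\n")

print(f"mean estimated capacity: K = {result['capacity'].K.mean():.2f}\n")
print("The window effect is highly significant while the focused task "
      "contrast is not:\ncoupling rose after the stimulus in every task, so "
      "it is not specific to memory.")
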