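"""Sliding-window category decoding with 10-fold cross-validation.

Builds per-image trial-averaged population vectors in 100-ms windows
stepped over the trial and reports the accuracy of the logistic decoder
before and after the response latency.  Pre-onset windows should decode
at chance (~0.5); post-latency windows well above it.
"""

from popsep import SyntheticConfig, decoding_timecourse, generate_dataset, sliding_windows

cfg = SyntheticConfig(
    n_neurons=30,
    images_per_category=30,
    trials_per_image=8,
    category_contrast=4.0,
    selective_fraction=0.5,
    latency_mean=50.0,
    latency_sd=10.0,
    seed=2,
)
dataset = generate_dataset(cfg)
windows = sliding_windows(-100.0, 300.0, width=100.0, step=50.0)
tc = decoding_timecourse(dataset, windows, k=10, seed=7, reg=1.0)

print("window start (ms)   CV accuracy")
for start, acc in zip(tc.window_starts, tc.accuracy):
    bar = "#" * int(40 * acc)
    print(f"{start:>12.0f}        {acc:.3f}  {bar}")
print(
    "\nAccuracy is the mean over 10 stratified folds of correct cat/dog"
    "\ndecisions on held-out images; folds are identical across windows,"
    "\nso differences between rows reflect only the windowed rates."
)
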