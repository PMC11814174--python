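"""Mahalanobis category separation over time: flat vs ramping codes.

Simulates a TEO-like population (category contrast constant after
response onset) and a TE-like population (contrast ramping within the
trial), computes the Mahalanobis distance D between the cat and dog
mean population vectors in sliding windows, and applies the
Mann-Whitney early-vs-late contrast to the ramping population.
"""

from popsep import (
    SyntheticConfig,
    generate_dataset,
    mannwhitney_windows,
    separation_timecourse,
    sliding_windows,
)

windows = sliding_windows(0.0, 350.0, width=100.0, step=25.0)
for name, profile, contrast, gain in (
    ("TEO-like (step)", "step", 1.5, 1.0),
    ("TE-like (ramp)", "ramp", 2.5, 1.5),
):
    cfg = SyntheticConfig(
        n_neurons=40,
        images_per_category=40,
        trials_per_image=10,
        profile=profile,
        ramp_end=255.0,
        category_contrast=contrast,
        training_gain=gain,
        selective_fraction=0.4,
        latency_mean=40.0,
        latency_sd=10.0,
        seed=3,
    )
    tc = separation_timecourse(generate_dataset(cfg), windows, inversion="ridge")
    print(f"\n{name}")
    print("window start (ms)   Mahalanobis D")
    for start, D in zip(tc.window_starts, tc.distance):
        print(f"{start:>12.0f}        {D:.3f}  " + "#" * int(8 * D))
    if profile == "ramp":
        rep = mannwhitney_windows(tc, (0.0, 100.0), (250.0, 350.0), alternative="greater")
        print(
            f"late (250-350 ms starts) vs early (0-100 ms starts): "
            f"U={rep.statistic:.0f}, one-sided p={rep.p_value:.4f}"
        )
# The step population's D curve is level once windows clear the response
# latency, while the ramping population roughly doubles its separation
# between the early and late window groups.  (Note that D samples from
# overlapping windows are autocorrelated, so rank tests on them should
# be read with care; see docs/methods.md.)
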