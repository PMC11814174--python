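import numpy as np
import pytest

from popsep import SpikeDataset, StimulusImage, SyntheticConfig, TrialRecord, generate_dataset


def make_dataset(spikes, categories, analysis_window=(-300.0, 400.0), trials_per_image=None,
                 area="TEO", session="pre"):
    """Build a small dataset by hand.

    ``spikes``: nested mapping image_id -> list of trials, each trial a
    mapping neuron_id -> spike time list.  ``categories``: image_id ->
    'cat'/'dog'.
    """
    neuron_ids = sorted({n for trials in spikes.values() for t in trials for n in t})
    stimuli = [StimulusImage(i, categories[i]) for i in spikes]
    trials = []
    k = 0
    for image_id, trial_list in spikes.items():
        for tmap in trial_list:
            full = {n: np.asarray(sorted(tmap.get(n, [])), dtype=float) for n in neuron_ids}
            trials.append(
                TrialRecord(f"t{k:04d}", image_id, 375.0, full)
            )
            k += 1
    return SpikeDataset(
        area=area,
        session=session,
        monkey_id="M0",
        neuron_ids=neuron_ids,
        stimuli=stimuli,
        trials=trials,
        analysis_window=analysis_window,
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A modest step-profile dataset reused by several suites."""
    cfg = SyntheticConfig(
        n_neurons=12,
        images_per_category=15,
        trials_per_image=6,
        latency_mean=60.0,
        latency_sd=10.0,
        category_contrast=6.0,
        selective_fraction=0.5,
        seed=42,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def tiny_dataset():
    """2 neurons, 4 images, 2 trials each, hand-written spikes."""
    spikes = {
        "c1": [{"nA": [-50.0, 10.0, 120.0], "nB": [30.0]},
               {"nA": [5.0], "nB": []}],
        "c2": [{"nA": [], "nB": [80.0, 90.0]},
               {"nA": [200.0], "nB": [15.0]}],
        "d1": [{"nA": [12.0, 14.0], "nB": [-100.0]},
               {"nA": [], "nB": [250.0]}],
        "d2": [{"nA": [33.0], "nB": [60.0, 61.0, 62.0]},
               {"nA": [-20.0, 300.0], "nB": []}],
    }
    cats = {"c1": "cat", "c2": "cat", "d1": "dog", "d2": "dog"}
    return make_dataset(spikes, cats)
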