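"""Per-image trial-averaged population vectors over sliding time windows.

The population vector for image ``i`` in window ``[t, t + dt)`` holds,
for each neuron, the spike count averaged over that image's trials and
divided by the window width — a firing rate in spikes/s.  Stacking the
520 image vectors gives the (images x neurons) matrix that the decoding
and separation analyses consume, with category labels cat=0 / dog=1.

Pseudo-populations concatenate neuron columns across datasets recorded
in different sessions or animals; rows are indexed by shared stimulus
identity, which is the only alignment available for non-simultaneous
recordings, and the provenance field records the sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import SpikeDataset, TimeWindow

LABEL_OF = {"cat": 0, "dog": 1}


class AlignmentError(ValueError):
    """Vector sets cannot be pooled: windows, images or labels differ."""


@dataclass
class PopulationVectorSet:
    """(n_images x N) matrix of windowed firing rates with category labels."""

    matrix: np.ndarray
    labels: np.ndarray          # 0 = cat, 1 = dog, one per row
    image_ids: list[str]
    neuron_ids: list[str]
    window: TimeWindow
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, N = self.matrix.shape
        if len(self.labels) != n or len(self.image_ids) != n or len(self.neuron_ids) != N:
            raise ValueError("inconsistent matrix / label / id dimensions")
        if np.any(self.matrix < 0):
            raise ValueError("firing rates must be non-negative")

    @property
    def n_images(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[1]

    def class_rows(self, label: int) -> np.ndarray:
        return self.matrix[self.labels == label]


def sliding_windows(
    start_min: float, start_max: float, width: float = 100.0, step: float = 1.0
) -> list[TimeWindow]:
    """Windows of fixed ``width`` with starts start_min, +step, ... <= start_max."""
    if start_min > start_max:
        raise ValueError("start_min must be <= start_max")
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    n = int(np.floor((start_max - start_min) / step + 1e-9)) + 1
    return [TimeWindow(start_min + k * step, width) for k in range(n)]


def population_vectors(dataset: SpikeDataset, window: TimeWindow) -> PopulationVectorSet:
    """Trial-averaged windowed rate matrix for one dataset and window.

    Entry (i, n) = mean over trials of image i of the spike count of
    neuron n in the half-open window, divided by the window width in s.
    """
    _check_window(dataset, window)
    return _vectors_from_counts(dataset, _image_counts(dataset, window), window)


def population_vector_stack(
    dataset: SpikeDataset, windows: list[TimeWindow]
) -> list[PopulationVectorSet]:
    """Population vectors for many windows, sharing one pass over the spikes.

    Equivalent to ``[population_vectors(dataset, w) for w in windows]``
    but bins the flattened spike arrays once; used by the time-course
    analyses where hundreds of 1-ms-stepped windows overlap heavily.
    """
    for w in windows:
        _check_window(dataset, w)
    flat = dataset.flat_spikes()
    time = flat["time"]
    image_idx = flat["image_idx"]
    neuron_idx = flat["neuron_idx"]
    n_images, n_neurons = len(dataset.stimuli), dataset.n_neurons
    out = []
    for w in windows:
        lo = np.searchsorted(time, w.start, side="left")
        hi = np.searchsorted(time, w.end, side="left")
        counts = np.zeros(n_images * n_neurons)
        if hi > lo:
            code = image_idx[lo:hi] * n_neurons + neuron_idx[lo:hi]
            counts = np.bincount(code, minlength=n_images * n_neurons).astype(float)
        out.append(
            _vectors_from_counts(dataset, counts.reshape(n_images, n_neurons), w)
        )
    return out


def _check_window(dataset: SpikeDataset, window: TimeWindow) -> None:
    lo, hi = dataset.analysis_window
    if window.start < lo or window.end > hi:
        raise ValueError(
            f"window [{window.start}, {window.end}) outside analysis window "
            f"[{lo}, {hi}] of dataset {dataset.dataset_id}"
        )


def _image_counts(dataset: SpikeDataset, window: TimeWindow) -> np.ndarray:
    flat = dataset.flat_spikes()
    time = flat["time"]
    n_images, n_neurons = len(dataset.stimuli), dataset.n_neurons
    lo = np.searchsorted(time, window.start, side="left")
    hi = np.searchsorted(time, window.end, side="left")
    if hi <= lo:
        return np.zeros((n_images, n_neurons))
    code = flat["image_idx"][lo:hi] * n_neurons + flat["neuron_idx"][lo:hi]
    return (
        np.bincount(code, minlength=n_images * n_neurons)
        .reshape(n_images, n_neurons)
        .astype(float)
    )


def _vectors_from_counts(
    dataset: SpikeDataset, counts: np.ndarray, window: TimeWindow
) -> PopulationVectorSet:
    tpi = dataset.flat_spikes()["trials_per_image"]
    rates = counts / tpi[:, None] / window.width_s
    labels = np.array([LABEL_OF[s.category] for s in dataset.stimuli])
    return PopulationVectorSet(
        matrix=rates,
        labels=labels,
        image_ids=dataset.image_ids,
        neuron_ids=list(dataset.neuron_ids),
        window=window,
        provenance=[dataset.dataset_id],
    )


def pool_pseudopopulation(vector_sets: list[PopulationVectorSet]) -> PopulationVectorSet:
    """Concatenate neuron columns of sets sharing window and stimulus set.

    Neuron ids are prefixed with their source dataset id so pooled
    columns stay unambiguous; rows (images) are untouched.
    """
    if not vector_sets:
        raise ValueError("nothing to pool")
    ref = vector_sets[0]
    for vs in vector_sets[1:]:
        if vs.window != ref.window:
            raise AlignmentError(f"window mismatch: {vs.window} vs {ref.window}")
        if vs.image_ids != ref.image_ids:
            raise AlignmentError("image sets differ between vector sets")
        if not np.array_equal(vs.labels, ref.labels):
            raise AlignmentError("label order differs between vector sets")
    matrix = np.hstack([vs.matrix for vs in vector_sets])
    prefixes = [
        str(vs.provenance[0]) if vs.provenance else f"set{k}"
        for k, vs in enumerate(vector_sets)
    ]
    if len(set(prefixes)) < len(prefixes):  # e.g. pooling a set with itself
        prefixes = [f"{p}[{k}]" for k, p in enumerate(prefixes)]
    neuron_ids = [
        f"{prefixes[k]}/{nid}"
        for k, vs in enumerate(vector_sets)
        for nid in vs.neuron_ids
    ]
    provenance = [p for vs in vector_sets for p in vs.provenance]
    return PopulationVectorSet(
        matrix=matrix,
        labels=ref.labels.copy(),
        image_ids=list(ref.image_ids),
        neuron_ids=neuron_ids,
        window=ref.window,
        provenance=provenance,
    )
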