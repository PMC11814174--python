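"""Inhomogeneous-Poisson generator for category-selective IT-like populations.

Emulates the statistical structure the downstream analyses assume:
two stimulus categories (cat/dog) with many images each, a handful of
trials per image, Poisson spiking with a per-neuron baseline, response
latency and visual gain, and a category-driven rate offset carried by a
selective subset of neurons.  The category contrast is either constant
after response onset (``step``, a TEO-like temporally flat code) or grows
linearly from latency to ``ramp_end`` (``ramp``, a TE-like code whose
category separation builds up within the trial).  A ``training_gain``
multiplier on the contrast models the post-training enhancement seen in
TE.

The rate of neuron ``n`` on any trial of image ``i`` is

    lam_ni(t) = max(0, b_n + 1[t >= L_n] * (g_n + s_n * c_i * p_n(t) + eps_ni))

with baseline ``b_n``, latency ``L_n``, gain ``g_n``, selectivity
``s_n in {0, +/- contrast * training_gain}``, category sign ``c_i = +1/2``
for dog and ``-1/2`` for cat, temporal profile ``p_n(t)`` and a per
(neuron, image) idiosyncratic offset ``eps_ni`` that makes images within
a category similar but not identical.

Reproducibility: one named RNG stream per (neuron, trial) plus one
structure stream for the population parameters, all derived from
``config.seed`` via ``numpy.random.SeedSequence`` spawn keys, so spike
trains are bit-identical across runs and independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .data_model import SpikeDataset, StimulusImage, TimeWindow, TrialRecord


class ConfigError(ValueError):
    """Invalid synthetic configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the generative model (rates in spikes/s, times in ms).

    Defaults mirror the recorded study conditions: 260 images per
    category, population mean firing in the 2-5 spikes/s range, response
    latencies well under 100 ms, and a 350-400 ms stimulus presentation
    analysed over a [-300, 500] ms peri-onset epoch.
    """

    n_neurons: int = 50
    images_per_category: int = 260
    trials_per_image: int = 10
    baseline_rate_mean: float = 4.0
    baseline_rate_sd: float = 1.5
    latency_mean: float = 65.0
    latency_sd: float = 15.0
    response_gain_mean: float = 8.0
    response_gain_sd: float = 3.0
    category_contrast: float = 3.0
    selective_fraction: float = 0.4
    profile: Literal["step", "ramp"] = "step"
    ramp_end: float = 255.0
    training_gain: float = 1.0
    image_idiosyncrasy_sd: float = 1.5
    seed: int = 0
    epoch: tuple[float, float] = (-300.0, 500.0)
    area: str = "TEO"
    session: str = "pre"
    monkey_id: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_neurons <= 0 or self.images_per_category <= 0 or self.trials_per_image <= 0:
            raise ConfigError("n_neurons, images_per_category and trials_per_image must be positive")
        if not 0.0 <= self.selective_fraction <= 1.0:
            raise ConfigError("selective_fraction must lie in [0, 1]")
        if not self.training_gain > 0:
            raise ConfigError("training_gain must be > 0")
        if self.profile not in ("step", "ramp"):
            raise ConfigError(f"unknown profile {self.profile!r}")
        if not self.epoch[0] < self.epoch[1]:
            raise ConfigError("epoch must be a non-empty interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch"] = list(self.epoch)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "epoch" in d:
            d["epoch"] = tuple(float(x) for x in d["epoch"])
        return cls(**d)


@dataclass
class PopulationStructure:
    """Realised per-neuron parameters and per-(neuron, image) offsets."""

    baseline: np.ndarray       # (N,) spikes/s, truncated at 0
    latency: np.ndarray        # (N,) ms, truncated at 0
    gain: np.ndarray           # (N,) spikes/s
    selectivity: np.ndarray    # (N,) signed contrast, 0 for non-selective
    idiosyncrasy: np.ndarray   # (N, n_images) spikes/s
    category_sign: np.ndarray  # (n_images,) +0.5 dog / -0.5 cat
    image_ids: list = field(default_factory=list)
    categories: list = field(default_factory=list)


def draw_structure(config: SyntheticConfig) -> PopulationStructure:
    """Draw the population parameters from the structure RNG stream.

    Deterministic in ``config.seed``; shared by :func:`generate_dataset`
    and :func:`expected_window_separation` so the analytic oracle refers
    to exactly the population that was simulated.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    )
    n = config.n_neurons
    baseline = np.maximum(
        0.0, rng.normal(config.baseline_rate_mean, config.baseline_rate_sd, n)
    )
    latency = np.maximum(0.0, rng.normal(config.latency_mean, config.latency_sd, n))
    gain = np.maximum(0.0, rng.normal(config.response_gain_mean, config.response_gain_sd, n))
    selective = rng.random(n) < config.selective_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    selectivity = np.where(
        selective, sign * config.category_contrast * config.training_gain, 0.0
    )
    n_images = 2 * config.images_per_category
    idio = rng.normal(0.0, config.image_idiosyncrasy_sd, (n, n_images))
    image_ids = [f"cat{i:04d}" for i in range(config.images_per_category)] + [
        f"dog{i:04d}" for i in range(config.images_per_category)
    ]
    categories = ["cat"] * config.images_per_category + ["dog"] * config.images_per_category
    c = np.array([-0.5] * config.images_per_category + [0.5] * config.images_per_category)
    return PopulationStructure(baseline, latency, gain, selectivity, idio, c, image_ids, categories)


def _profile_integral(config: SyntheticConfig, latency: float, a: float, b: float) -> float:
    """Integral of 1[t>=L] * p(t) over [a, b] in ms.

    ``p`` is 1 after latency for the step profile; for the ramp profile it
    rises linearly from 0 at latency to 1 at ``ramp_end`` and stays at 1.
    """
    lo = max(a, latency)
    if lo >= b:
        return 0.0
    if config.profile == "step" or config.ramp_end <= latency:
        return b - lo
    re = config.ramp_end
    total = 0.0
    ramp_hi = min(b, re)
    if ramp_hi > lo:  # linear section: p(t) = (t - L) / (re - L)
        total += ((ramp_hi - latency) ** 2 - (lo - latency) ** 2) / (2.0 * (re - latency))
    if b > re:
        total += b - max(lo, re)
    return total


def _post_latency_fraction(latency: float, a: float, b: float) -> float:
    return max(0.0, b - max(a, latency)) / (b - a)


def _rate_breakpoints(config: SyntheticConfig, latency: float) -> np.ndarray:
    t0, t1 = config.epoch
    pts = [t0, t1]
    if t0 < latency < t1:
        pts.append(latency)
    if config.profile == "ramp" and t0 < config.ramp_end < t1:
        pts.append(config.ramp_end)
    return np.unique(np.asarray(pts, dtype=float))


def generate_dataset(config: SyntheticConfig) -> SpikeDataset:
    """Simulate a :class:`SpikeDataset` under the generative model.

    Spike trains are inhomogeneous Poisson, sampled by thinning against
    the piecewise-linear rate ceiling of each (neuron, image) rate
    function.  Runtime scales with the expected spike count; a
    50-neuron, 80-image, 10-trial dataset takes on the order of a second.
    """
    struct = draw_structure(config)
    t0, t1 = config.epoch
    T_ms = t1 - t0
    n_images = 2 * config.images_per_category
    stimuli = [
        StimulusImage(struct.image_ids[i], struct.categories[i]) for i in range(n_images)
    ]

    trials: list[TrialRecord] = []
    neuron_ids = [f"n{j:03d}" for j in range(config.n_neurons)]
    seed = config.seed

    # Pre-compute per-(neuron, image) rate pieces. After latency the rate is
    # base2 + slope-scaled profile:  lam = b            (t < L)
    #                                lam = max(0, b + g + eps + s*c*p(t))  (t >= L)
    base = struct.baseline
    post_flat = base[:, None] + struct.gain[:, None] + struct.idiosyncrasy  # (N, I)
    cat_amp = struct.selectivity[:, None] * struct.category_sign[None, :]   # (N, I)

    trial_counter = 0
    for i in range(n_images):
        for _ in range(config.trials_per_image):
            spike_map: dict[str, np.ndarray] = {}
            for j in range(config.n_neurons):
                ss = np.random.SeedSequence(seed, spawn_key=(1, j, trial_counter))
                rng = np.random.Generator(np.random.PCG64(ss))
                L = struct.latency[j]
                b = base[j]
                pf = post_flat[j, i]
                ca = cat_amp[j, i]
                # rate ceiling over the epoch (profile in [0, 1])
                lam_max = max(b, pf + max(ca, 0.0), pf, 0.0)
                if lam_max <= 0:
                    spike_map[neuron_ids[j]] = np.empty(0)
                    continue
                n_cand = rng.poisson(lam_max * T_ms / 1000.0)
                if n_cand == 0:
                    spike_map[neuron_ids[j]] = np.empty(0)
                    continue
                t = t0 + rng.random(n_cand) * T_ms
                u = rng.random(n_cand)
                if config.profile == "step" or config.ramp_end <= L:
                    p = (t >= L).astype(float)
                else:
                    p = np.clip((t - L) / (config.ramp_end - L), 0.0, 1.0)
                    p[t < L] = 0.0
                lam = np.where(t < L, b, np.maximum(0.0, pf + ca * p))
                keep = u * lam_max < lam
                st = np.sort(t[keep])
                st = st[(st >= t0) & (st <= t1)]
                # strictly increasing: drop exact duplicates (measure zero)
                if st.size > 1:
                    st = st[np.concatenate(([True], np.diff(st) > 0))]
                spike_map[neuron_ids[j]] = st
            trials.append(
                TrialRecord(
                    trial_id=f"t{trial_counter:06d}",
                    image_id=struct.image_ids[i],
                    presentation_duration=375.0,
                    spike_times=spike_map,
                )
            )
            trial_counter += 1

    return SpikeDataset(
        area=config.area,
        session=config.session,
        monkey_id=config.monkey_id,
        neuron_ids=neuron_ids,
        stimuli=stimuli,
        trials=trials,
        analysis_window=(t0, t1),
    )


def expected_window_separation(
    config: SyntheticConfig, window: TimeWindow
) -> float:
    """Large-trial (population-scale) Mahalanobis distance for one window.

    Computes, for the realised population of ``config`` (same seed-derived
    parameters as :func:`generate_dataset`), the expected distance between
    the cat and dog mean rate vectors in the metric of the within-class
    covariance of per-image trial-averaged rates:

        D = sqrt( sum_n delta_n^2 / sigma_n^2 )

    where ``delta_n`` is the window-averaged category rate difference
    (selectivity times the profile integral over the window) and
    ``sigma_n^2`` the within-class variance of the per-image rate:
    Poisson count variance of the trial average plus the idiosyncratic
    rate variance scaled by the post-latency window fraction.  Rate
    truncation at zero is ignored (valid when baselines dominate the
    modulation).  Returns 0 for windows entirely before every latency.

    Note the scatter-matrix Mahalanobis distance computed by the
    separation module divides by no sample count; to compare an empirical
    estimate against this population value, rescale as described in the
    methods note.
    """
    t0, t1 = config.epoch
    if not (window.start >= t0 and window.end <= t1):
        raise ValueError(f"window {window} outside epoch {config.epoch}")
    struct = draw_structure(config)
    a, b = window.start, window.end
    width_s = window.width_s
    total = 0.0
    for j in range(config.n_neurons):
        L = struct.latency[j]
        delta = abs(struct.selectivity[j]) * _profile_integral(config, L, a, b) / window.width
        if delta == 0.0:
            continue
        f = _post_latency_fraction(L, a, b)
        # window-mean rate, category-averaged, idiosyncrasy-averaged
        lam_bar = struct.baseline[j] + struct.gain[j] * f
        var_poisson = lam_bar / (config.trials_per_image * width_s)
        var_idio = (config.image_idiosyncrasy_sd * f) ** 2
        total += delta**2 / (var_poisson + var_idio)
    return float(np.sqrt(total))
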