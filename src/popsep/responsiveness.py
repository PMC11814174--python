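"""Per-neuron visual responsiveness: rate functions, tests, classification.

A neuron is *visually responsive* if its firing rate increases or
decreases significantly during stimulus presentation for at least one
image (two-sided paired t-test on per-trial rates, baseline window vs
stimulus window), with Benjamini-Hochberg FDR correction across the
image tests.  Responsive neurons are classified by which category their
significant images belong to: only dog, only cat, both, or none.

Also provides the Gaussian-kernel density estimate of the firing-rate
function (10-ms bandwidth by default) and a threshold-crossing onset
latency rule (baseline mean + 3 SD sustained for 20 ms); the latency
rule's parameters are reported with every estimate because the rule
itself is a package convention, not a community standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import SpikeDataset, TimeWindow

#: Default test windows: baseline covers the pre-onset fixation epoch,
#: stimulus window the minimum presentation duration.
DEFAULT_BASELINE = TimeWindow(-200.0, 200.0)
DEFAULT_STIMULUS = TimeWindow(0.0, 350.0)

CLASSES = ("only_dog", "only_cat", "both", "none")


class InsufficientDataError(ValueError):
    pass


@dataclass
class RateFunction:
    """Trial-pooled KDE firing-rate estimate in spikes/s on a time grid."""

    time_grid: np.ndarray
    rate: np.ndarray
    bandwidth: float
    n_trials: int

    def integral(self) -> float:
        """Trapezoidal integral of the rate over the grid, in spikes.

        Equals the per-trial spike count when the grid extends at least a
        few bandwidths beyond the extreme spikes.
        """
        return float(np.trapezoid(self.rate, self.time_grid) / 1000.0)


@dataclass
class LatencyEstimate:
    """Onset latency in ms (or None) plus the threshold rule that produced it."""

    latency: float | None
    threshold_rule: dict


@dataclass
class ResponsivenessTable:
    """Per-neuron image-test results and responsiveness classes.

    ``p_values`` and ``significant`` are (neuron x image) frames;
    ``direction`` holds +1 (rate increase), -1 (decrease) or 0
    (untestable / not significant); ``classes`` maps neuron id to one of
    ``only_dog``, ``only_cat``, ``both``, ``none``.
    """

    p_values: pd.DataFrame
    significant: pd.DataFrame
    direction: pd.DataFrame
    classes: pd.Series
    alpha: float
    family: str
    baseline_window: TimeWindow = DEFAULT_BASELINE
    stimulus_window: TimeWindow = DEFAULT_STIMULUS
    degenerate: list = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    @property
    def n_neurons(self) -> int:
        return len(self.classes)

    @property
    def n_responsive(self) -> int:
        return int((self.classes != "none").sum())


def firing_rate_function(
    spike_times_per_trial: list[np.ndarray],
    bandwidth: float = 10.0,
    grid: np.ndarray | None = None,
) -> RateFunction:
    """Gaussian-kernel firing-rate function pooled over trials.

    rate(t) = (1000 / n_trials) * sum_spikes N(t; spike, bandwidth^2),
    in spikes/s with times in ms.  The numerical integral over a grid
    covering all spikes recovers the mean spike count per trial.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if len(spike_times_per_trial) == 0:
        raise InsufficientDataError("need at least one trial")
    if grid is None or len(grid) == 0:
        raise ValueError("a non-empty time grid is required")
    grid = np.asarray(grid, dtype=float)
    spikes = (
        np.concatenate([np.asarray(s, dtype=float) for s in spike_times_per_trial])
        if any(len(s) for s in spike_times_per_trial)
        else np.empty(0)
    )
    n_trials = len(spike_times_per_trial)
    if spikes.size == 0:
        return RateFunction(grid, np.zeros_like(grid), bandwidth, n_trials)
    z = (grid[:, None] - spikes[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (bandwidth * np.sqrt(2.0 * np.pi))
    return RateFunction(grid, 1000.0 * dens / n_trials, bandwidth, n_trials)


def _window_counts(dataset: SpikeDataset, window: TimeWindow) -> np.ndarray:
    """Spike counts per (trial, neuron) in a half-open window, vectorised."""
    flat = dataset.flat_spikes()
    time = flat["time"]
    lo = np.searchsorted(time, window.start, side="left")
    hi = np.searchsorted(time, window.end, side="left")
    counts = np.zeros((len(dataset.trials), dataset.n_neurons))
    if hi > lo:
        code = flat["trial_idx"][lo:hi] * dataset.n_neurons + flat["neuron_idx"][lo:hi]
        binc = np.bincount(code, minlength=counts.size)
        counts = binc.reshape(counts.shape).astype(float)
    return counts


def _paired_t(diffs: np.ndarray) -> float:
    """Two-sided paired t p-value on the differences; zero variance -> 1."""
    n = len(diffs)
    if n < 2:
        raise InsufficientDataError("paired t-test needs >= 2 trials")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return 1.0
    t = diffs.mean() / (sd / np.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), n - 1))


def image_responsiveness_test(
    dataset: SpikeDataset,
    neuron_id: str,
    image_id: str,
    baseline_window: TimeWindow = DEFAULT_BASELINE,
    stimulus_window: TimeWindow = DEFAULT_STIMULUS,
) -> tuple[float, int]:
    """Paired t-test of baseline vs stimulus firing rate for one image.

    Rates (counts / window width) are compared per trial; returns the
    two-sided p-value and the direction of the mean change (+1 increase,
    -1 decrease, 0 when all per-trial differences are exactly zero, in
    which case p = 1 by the degenerate-variance convention).
    """
    trials = dataset.trials_for_image(image_id)
    if len(trials) < 2:
        raise InsufficientDataError(
            f"image {image_id!r} has {len(trials)} trial(s); need >= 2"
        )
    if neuron_id not in dataset.neuron_ids:
        raise KeyError(f"unknown neuron_id {neuron_id!r}")
    base = np.array(
        [_count_in(t.spike_times[neuron_id], baseline_window) for t in trials]
    ) / baseline_window.width_s
    stim = np.array(
        [_count_in(t.spike_times[neuron_id], stimulus_window) for t in trials]
    ) / stimulus_window.width_s
    diffs = stim - base
    p = _paired_t(diffs)
    direction = 0 if np.all(diffs == 0) else int(np.sign(diffs.mean()) or 0)
    return p, direction


def _count_in(spike_times: np.ndarray, window: TimeWindow) -> int:
    return int(
        np.searchsorted(spike_times, window.end, side="left")
        - np.searchsorted(spike_times, window.start, side="left")
    )


def bh_adjust(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at FDR level ``alpha``.

    Rejects hypotheses 1..k* in sorted order, k* = max{k : p_(k) <= k*alpha/m}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def classify_neurons(
    dataset: SpikeDataset,
    baseline_window: TimeWindow = DEFAULT_BASELINE,
    stimulus_window: TimeWindow = DEFAULT_STIMULUS,
    alpha: float = 0.05,
    family: str = "per_neuron",
) -> ResponsivenessTable:
    """Test every (neuron, image) pair and classify neurons.

    ``family`` chooses the BH correction family: ``"per_neuron"`` (the
    default; the image tests of one neuron form one family, keeping each
    neuron's classification self-contained) or ``"global"`` (one family
    across all neuron x image tests).
    """
    if family not in ("per_neuron", "global"):
        raise ValueError(f"family must be 'per_neuron' or 'global', got {family!r}")
    n_neurons = dataset.n_neurons
    image_ids = dataset.image_ids
    n_images = len(image_ids)
    flat = dataset.flat_spikes()
    trials_per_image = flat["trials_per_image"]
    if np.any(trials_per_image < 2):
        raise InsufficientDataError("every image needs >= 2 trials for the paired test")

    base_counts = _window_counts(dataset, baseline_window)  # (trials, neurons)
    stim_counts = _window_counts(dataset, stimulus_window)
    diffs = (
        stim_counts / stimulus_window.width_s - base_counts / baseline_window.width_s
    )

    p_mat = np.ones((n_neurons, n_images))
    d_mat = np.zeros((n_neurons, n_images), dtype=int)
    degenerate: list[tuple[str, str]] = []
    trial_image = flat["trial_image_idx"]
    uniform = len(set(trials_per_image.tolist())) == 1
    if uniform:
        k = int(trials_per_image[0])
        # (images, trials, neurons) via stable grouping of trials by image
        order = np.argsort(trial_image, kind="stable")
        grouped = diffs[order].reshape(n_images, k, n_neurons)
        mean = grouped.mean(axis=1)
        sd = grouped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean / (sd / np.sqrt(k))
        pv = 2.0 * stats.t.sf(np.abs(tstat), k - 1)
        pv = np.where(sd == 0.0, 1.0, pv)
        p_mat = pv.T
        d_mat = np.sign(mean).astype(int).T
    else:
        for ii, img in enumerate(image_ids):
            rows = np.flatnonzero(trial_image == ii)
            dd = diffs[rows]  # (trials_i, neurons)
            mean = dd.mean(axis=0)
            sd = dd.std(axis=0, ddof=1)
            k = len(rows)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = mean / (sd / np.sqrt(k))
            pv = 2.0 * stats.t.sf(np.abs(tstat), k - 1)
            p_mat[:, ii] = np.where(sd == 0.0, 1.0, pv)
            d_mat[:, ii] = np.sign(mean).astype(int)
    for j, nid in enumerate(dataset.neuron_ids):
        for ii in np.flatnonzero(p_mat[j] == 1.0):
            if d_mat[j, ii] == 0:
                degenerate.append((nid, image_ids[ii]))

    if family == "per_neuron":
        sig = np.vstack([bh_adjust(p_mat[j], alpha) for j in range(n_neurons)])
    else:
        sig = bh_adjust(p_mat.ravel(), alpha).reshape(p_mat.shape)

    cats = np.array([dataset.category_of(i) for i in image_ids])
    is_dog = cats == "dog"
    classes = []
    for j in range(n_neurons):
        n_dog = int(np.sum(sig[j] & is_dog))
        n_cat = int(np.sum(sig[j] & ~is_dog))
        if n_dog and n_cat:
            classes.append("both")
        elif n_dog:
            classes.append("only_dog")
        elif n_cat:
            classes.append("only_cat")
        else:
            classes.append("none")

    idx = pd.Index(dataset.neuron_ids, name="neuron_id")
    cols = pd.Index(image_ids, name="image_id")
    return ResponsivenessTable(
        p_values=pd.DataFrame(p_mat, index=idx, columns=cols),
        significant=pd.DataFrame(sig, index=idx, columns=cols),
        direction=pd.DataFrame(d_mat, index=idx, columns=cols),
        classes=pd.Series(classes, index=idx, name="class"),
        alpha=alpha,
        family=family,
        baseline_window=baseline_window,
        stimulus_window=stimulus_window,
        degenerate=degenerate,
    )


def summarize_responsiveness(tables) -> dict:
    """Pool responsiveness tables (or raw class counts) into percentages.

    Each element of ``tables`` is a :class:`ResponsivenessTable` or a
    mapping with keys ``only_dog``, ``only_cat``, ``both``, ``none``.
    Returns the pooled percent responsive, 100 * sum(total - none) /
    sum(total), both unrounded and rounded to a whole percent
    (half away from zero, as printed summaries round).
    """
    if not tables:
        raise ValueError("summarize_responsiveness needs at least one table")
    total = 0
    none = 0
    for t in tables:
        counts = t.class_counts() if isinstance(t, ResponsivenessTable) else dict(t)
        for c in CLASSES:
            if c not in counts:
                raise ValueError(f"class counts missing {c!r}")
        total += sum(int(counts[c]) for c in CLASSES)
        none += int(counts["none"])
    if total == 0:
        raise ValueError("pooled tables contain zero neurons")
    pct = 100.0 * (total - none) / total
    return {
        "n_total": total,
        "n_responsive": total - none,
        "percent_responsive": pct,
        "percent_responsive_rounded": int(np.floor(pct + 0.5)),
    }


def neuron_latencies(
    dataset: SpikeDataset,
    baseline_window: TimeWindow = DEFAULT_BASELINE,
    bandwidth: float = 10.0,
    grid_step: float = 1.0,
    threshold_sd: float = 3.0,
    min_duration: float = 20.0,
) -> pd.Series:
    """Onset latency per neuron from its trial-pooled KDE rate function.

    Spikes are pooled across every presentation (all images); NaN where
    the threshold rule finds no sustained crossing.
    """
    lo, hi = dataset.analysis_window
    grid = np.arange(lo, hi + grid_step, grid_step)
    out = {}
    n_trials = len(dataset.trials)
    flat = dataset.flat_spikes()
    for j, nid in enumerate(dataset.neuron_ids):
        spikes = flat["time"][flat["neuron_idx"] == j]
        pooled = firing_rate_function([spikes], bandwidth=bandwidth, grid=grid)
        rf = RateFunction(grid, pooled.rate / n_trials, bandwidth, n_trials)
        est = onset_latency(rf, baseline_window, threshold_sd, min_duration)
        out[nid] = np.nan if est.latency is None else est.latency
    return pd.Series(out, name="latency_ms")


def onset_latency(
    rate_function: RateFunction,
    baseline_window: TimeWindow = DEFAULT_BASELINE,
    threshold_sd: float = 3.0,
    min_duration: float = 20.0,
) -> LatencyEstimate:
    """Threshold-crossing onset latency from a KDE rate function.

    The earliest t >= 0 at which the rate exceeds (baseline mean +
    ``threshold_sd`` * baseline SD) continuously for at least
    ``min_duration`` ms; None if no such crossing exists (including the
    degenerate flat-rate, zero-SD case, which cannot define a
    threshold).
    """
    rule = {
        "method": "baseline_threshold",
        "threshold_sd": threshold_sd,
        "min_duration_ms": min_duration,
        "baseline_window": [baseline_window.start, baseline_window.end],
    }
    t = rate_function.time_grid
    r = rate_function.rate
    in_base = (t >= baseline_window.start) & (t < baseline_window.end)
    if in_base.sum() < 2:
        raise ValueError("rate function does not cover the baseline window")
    mu, sd = r[in_base].mean(), r[in_base].std(ddof=0)
    if sd == 0.0 and np.all(r == r[0]):
        return LatencyEstimate(None, rule)
    thresh = mu + threshold_sd * sd
    post = t >= 0
    tp, rp = t[post], r[post]
    above = rp > thresh
    i = 0
    n = len(tp)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if tp[j] - tp[i] >= min_duration:
                return LatencyEstimate(float(tp[i]), rule)
            i = j + 1
        else:
            i += 1
    return LatencyEstimate(None, rule)
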