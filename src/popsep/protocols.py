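"""Canned desk-scale study protocols and their summary statistics.

These functions bundle the package's standard validation experiments:
the TEO-like (temporally flat) versus TE-like (within-trial ramp)
window-start contrast, decoding chance calibration under label
permutation, parameter recovery of the analytic window separation, the
null false-positive control of the responsiveness test, and the pooled
responsiveness percentages recomputed from the published per-monkey
neuron counts of the recorded study.  Everything here is computed by
running the library; nothing is tabulated output.

Scales are deliberately reduced relative to the original recordings
(50 neurons, 40 images per category, 10 trials per image for the
contrast experiments) so a full protocol sweep runs in minutes on one
CPU; the methods note discusses what that implies.
"""

from __future__ import annotations

import numpy as np

from .data_model import TimeWindow
from .compare import mannwhitney_windows
from .decoding import decoding_timecourse
from .popvec import sliding_windows
from .responsiveness import bh_adjust, classify_neurons, firing_rate_function
from .separation import mahalanobis_distance, scatter_matrices
from .popvec import population_vectors
from .synthetic import SyntheticConfig, expected_window_separation, generate_dataset

#: Published per-monkey neuron classification counts
#: (only_dog, only_cat, both, none), keyed by monkey / area / session.
STUDY_CLASS_COUNTS = {
    ("X", "TEO", "pre"): {"only_dog": 3, "only_cat": 1, "both": 84, "none": 5},
    ("X", "TEO", "post"): {"only_dog": 1, "only_cat": 1, "both": 94, "none": 1},
    ("X", "TE", "pre"): {"only_dog": 8, "only_cat": 7, "both": 61, "none": 74},
    ("X", "TE", "post"): {"only_dog": 8, "only_cat": 5, "both": 45, "none": 77},
    ("R", "TE", "pre"): {"only_dog": 7, "only_cat": 6, "both": 89, "none": 46},
    ("R", "TE", "post"): {"only_dog": 9, "only_cat": 4, "both": 92, "none": 32},
    ("L", "TEO", "pre"): {"only_dog": 1, "only_cat": 3, "both": 57, "none": 17},
    ("L", "TEO", "post"): {"only_dog": 3, "only_cat": 2, "both": 51, "none": 17},
    ("L", "TE", "pre"): {"only_dog": 2, "only_cat": 6, "both": 30, "none": 19},
    ("L", "TE", "post"): {"only_dog": 3, "only_cat": 8, "both": 23, "none": 35},
}

#: Reduced simulation scale for the window-contrast experiments.
REDUCED_SCALE = dict(n_neurons=50, images_per_category=40, trials_per_image=10)

#: Window-start ranges of the early/late Mahalanobis contrast (ms).
EARLY_RANGE = (0.0, 100.0)
LATE_RANGE = (250.0, 350.0)


def pooled_class_counts(area: str, session: str) -> list[dict]:
    """All monkeys' class-count tables for one area x session."""
    return [
        counts
        for (m, a, s), counts in STUDY_CLASS_COUNTS.items()
        if a == area and s == session
    ]


def teo_step_config(seed: int) -> SyntheticConfig:
    """TEO-like conditions: flat (step) category contrast after onset.

    Latency 40 +- 10 ms sits at the short end of the latencies reported
    for the recorded populations; the contrast is weaker than the
    TE-like configuration, matching the consistently smaller category
    separation observed in TEO.
    """
    return SyntheticConfig(
        profile="step",
        category_contrast=1.5,
        training_gain=1.0,
        selective_fraction=0.4,
        latency_mean=40.0,
        latency_sd=10.0,
        area="TEO",
        seed=seed,
        **REDUCED_SCALE,
    )


def te_ramp_config(seed: int) -> SyntheticConfig:
    """TE-like conditions: contrast ramps from latency to 255 ms, with a
    post-training gain of 1.5."""
    return SyntheticConfig(
        profile="ramp",
        ramp_end=255.0,
        category_contrast=2.5,
        training_gain=1.5,
        selective_fraction=0.4,
        latency_mean=40.0,
        latency_sd=10.0,
        area="TE",
        session="post",
        seed=seed,
    **REDUCED_SCALE,
    )


def window_contrast_rates(base_seed: int, n_runs: int = 20) -> dict:
    """Early-vs-late Mahalanobis Mann-Whitney outcomes over seeded runs.

    For each seed, generates one TEO-like and one TE-like dataset,
    computes the D time course over 1-ms-stepped window starts in the
    early and late ranges, and applies the Mann-Whitney test (two-sided
    for the flatness check, one-sided 'greater' for the increase).
    Returns the fraction of runs with step p > 0.05 and ramp p < 0.05.
    """
    from .separation import separation_timecourse

    windows = sliding_windows(*EARLY_RANGE) + sliding_windows(*LATE_RANGE)
    step_p, ramp_p = [], []
    for i in range(n_runs):
        seed = base_seed + i
        tc_step = separation_timecourse(generate_dataset(teo_step_config(seed)), windows)
        tc_ramp = separation_timecourse(generate_dataset(te_ramp_config(seed)), windows)
        step_p.append(
            mannwhitney_windows(tc_step, EARLY_RANGE, LATE_RANGE, "two-sided").p_value
        )
        ramp_p.append(
            mannwhitney_windows(tc_ramp, EARLY_RANGE, LATE_RANGE, "greater").p_value
        )
    step_p, ramp_p = np.array(step_p), np.array(ramp_p)
    return {
        "n_runs": n_runs,
        "step_p_values": step_p,
        "ramp_p_values": ramp_p,
        "step_nonsignificant_rate": float(np.mean(step_p > 0.05)),
        "ramp_significant_rate": float(np.mean(ramp_p < 0.05)),
    }


def chance_calibration(seed: int) -> dict:
    """Decoding on label-permuted data: fraction of windows inside the
    pointwise 99% binomial band around 0.5."""
    cfg = SyntheticConfig(
        n_neurons=30,
        images_per_category=40,
        trials_per_image=10,
        category_contrast=4.0,
        selective_fraction=0.5,
        latency_mean=40.0,
        latency_sd=10.0,
        seed=seed,
    )
    ds = generate_dataset(cfg)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ds.stimuli))
    # permute category labels by shuffling which image carries which label
    cats = [s.category for s in ds.stimuli]
    from .data_model import StimulusImage

    ds.stimuli = [
        StimulusImage(s.image_id, cats[perm[i]]) for i, s in enumerate(ds.stimuli)
    ]
    ds.validate()
    windows = sliding_windows(-100.0, 300.0)
    tc = decoding_timecourse(ds, windows, k=10, seed=seed)
    n = len(ds.stimuli)
    half_width = 2.576 * np.sqrt(0.25 / n)
    inside = np.abs(tc.accuracy - 0.5) <= half_width
    return {
        "n_windows": len(windows),
        "n_images": n,
        "band_half_width": float(half_width),
        "within_band_fraction": float(np.mean(inside)),
        "accuracy": tc.accuracy,
    }


def parameter_recovery(seed: int, window_starts=(150.0, 200.0, 250.0)) -> dict:
    """Empirical sliding-window D against the analytic expectation.

    Simulates a 10-neuron, 100-images-per-category, 200-trials-per-image
    dataset, estimates the scatter-based Mahalanobis distance in each
    window, converts it to the population scale by the Wishart
    debiasing described in the methods note, and reports the relative
    error against :func:`expected_window_separation`.
    """
    cfg = SyntheticConfig(
        n_neurons=10,
        images_per_category=100,
        trials_per_image=200,
        selective_fraction=1.0,
        latency_mean=40.0,
        latency_sd=10.0,
        category_contrast=3.0,
        seed=seed,
    )
    ds = generate_dataset(cfg)
    n = 2 * cfg.images_per_category
    N = cfg.n_neurons
    errors = {}
    for start in window_starts:
        w = TimeWindow(start, 100.0)
        vs = population_vectors(ds, w)
        m1, m2, S_W, _ = scatter_matrices(vs)
        D_hat = mahalanobis_distance(m1, m2, S_W, "strict")
        d2_pop = D_hat**2 * (n - 2 - N - 1) - N * (2 / cfg.images_per_category)
        emp = float(np.sqrt(max(d2_pop, 0.0)))
        exp = expected_window_separation(cfg, w)
        errors[start] = abs(emp - exp) / exp
    return {
        "relative_errors": errors,
        "max_relative_error": float(max(errors.values())),
        "n_images": n,
        "trials_per_image": cfg.trials_per_image,
    }


def null_responsiveness(seed: int, n_neurons: int = 80) -> dict:
    """False-positive control: zero-signal data, 520 images per neuron."""
    cfg = SyntheticConfig(
        n_neurons=n_neurons,
        images_per_category=260,
        trials_per_image=5,
        baseline_rate_mean=5.0,
        baseline_rate_sd=1.0,
        response_gain_mean=0.0,
        response_gain_sd=0.0,
        category_contrast=0.0,
        image_idiosyncrasy_sd=0.0,
        seed=seed,
    )
    ds = generate_dataset(cfg)
    table = classify_neurons(ds, alpha=0.05)
    frac = table.n_responsive / table.n_neurons
    bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_neurons)
    return {
        "responsive_fraction": float(frac),
        "bound": float(bound),
        "alpha": 0.05,
        "n_neurons": n_neurons,
        "n_images": 520,
    }


def lda_identity_errors(seed: int, n_instances: int = 100) -> dict:
    """Closed form vs generalised eigenproblem and J = lambda = D^2.

    Random well-conditioned two-class instances; returns the worst
    relative disagreement across instances.
    """
    from scipy import linalg

    from .popvec import PopulationVectorSet

    rng = np.random.default_rng(seed)
    worst_cos = 1.0
    worst_rel = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(2, 8))
        n = int(rng.integers(N + 3, 40))
        mu1 = rng.uniform(2, 10, N)
        mu2 = mu1 + rng.normal(0, 1.5, N)
        A = rng.normal(0, 1, (N, N))
        X1 = np.abs(mu1 + rng.normal(0, 1, (n, N)) @ A * 0.3)
        X2 = np.abs(mu2 + rng.normal(0, 1, (n, N)) @ A * 0.3)
        X = np.vstack([X1, X2])
        vs = PopulationVectorSet(
            matrix=X,
            labels=np.array([0] * n + [1] * n),
            image_ids=[f"i{k}" for k in range(2 * n)],
            neuron_ids=[f"n{k}" for k in range(N)],
            window=TimeWindow(0.0, 100.0),
        )
        from .separation import fisher_criterion, lda_direction

        m1, m2, S_W, S_B = scatter_matrices(vs)
        w = lda_direction(m1, m2, S_W, "strict")
        evals, evecs = linalg.eigh(S_B, S_W)
        v = evecs[:, -1]
        cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        worst_cos = min(worst_cos, float(cos))
        D = mahalanobis_distance(m1, m2, S_W, "strict")
        J = fisher_criterion(w, S_W, S_B)
        lam = float(evals[-1])
        worst_rel = max(
            worst_rel,
            abs(J - lam) / lam,
            abs(J - D**2) / max(J, D**2),
        )
    return {
        "n_instances": n_instances,
        "min_cosine": worst_cos,
        "max_rel_error": float(worst_rel),
    }


def bh_definition_agreement(seed: int, n_vectors: int = 1000) -> dict:
    """BH implementation vs the literal step-up definition."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        alpha = float(rng.uniform(0.01, 0.2))
        order = np.argsort(p, kind="stable")
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_star = k
        brute = np.zeros(m, dtype=bool)
        brute[order[:k_star]] = True
        agree += bool(np.array_equal(bh_adjust(p, alpha), brute))
    return {"n_vectors": n_vectors, "agreement_fraction": agree / n_vectors}


def kde_mass_errors(seed: int, n_sets: int = 50) -> dict:
    """Mass conservation of the KDE rate function on random spike sets."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(-400.0, 500.0, 1801)
    worst = 0.0
    for _ in range(n_sets):
        n_trials = int(rng.integers(1, 8))
        trials = [
            np.sort(rng.uniform(-250, 350, rng.integers(1, 30))) for _ in range(n_trials)
        ]
        rf = firing_rate_function(trials, bandwidth=10.0, grid=grid)
        per_trial = sum(len(t) for t in trials) / n_trials
        worst = max(worst, abs(rf.integral() - per_trial) / per_trial)
    return {"n_sets": n_sets, "max_rel_error": float(worst)}
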