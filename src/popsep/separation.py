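"""Fisher linear discriminant separation of cat and dog population vectors.

For per-image population vectors x_n with class means m1 (cat) and
m2 (dog), the within-class scatter S_W = sum_k sum_{n in C_k}
(x_n - m_k)(x_n - m_k)^T and between-class scatter
S_B = (m2 - m1)(m2 - m1)^T define Fisher's criterion
J(w) = (w^T S_B w) / (w^T S_W w).  The maximiser is the top eigenvector
of S_W^{-1} S_B, available in closed form as w_hat prop S_W^{-1}(m2 - m1),
and the maximal criterion value equals the squared Mahalanobis distance
between the class means in the S_W metric:

    D = sqrt((m2 - m1)^T S_W^{-1} (m2 - m1)),   J(w_hat) = lambda = D^2.

These identities are asserted (1e-8 relative) whenever a
:class:`SeparationResult` is built.  S_W inversion is configurable:
``ridge`` (default; Tikhonov diagonal epsilon = 1e-6 * trace(S_W)/N),
``strict`` (plain solve, error if condition number > 1e12) or ``pinv``
(truncated pseudo-inverse).  With neuron counts approaching the number
of within-class degrees of freedom S_W is near-singular and a recorded
inversion policy keeps runs comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data_model import SpikeDataset, TimeWindow
from .popvec import (
    PopulationVectorSet,
    pool_pseudopopulation,
    population_vector_stack,
)

INVERSIONS = ("ridge", "strict", "pinv")
_COND_LIMIT = 1e12
_RIDGE_SCALE = 1e-6
_PINV_RTOL = 1e-10
_IDENTITY_RTOL = 1e-8


class SingularScatterError(np.linalg.LinAlgError):
    """S_W is rank-deficient beyond what the inversion policy allows."""


class DegenerateScatterError(ValueError):
    """A class has too few samples to form a scatter matrix."""


@dataclass
class SeparationResult:
    """LDA solution for one window: means, scatters, direction, J, D."""

    m1: np.ndarray
    m2: np.ndarray
    S_W: np.ndarray
    S_B: np.ndarray
    direction: np.ndarray        # w_hat, normalised so w^T S_W w = 1
    criterion: float             # J(w_hat)
    eigenvalue: float            # top generalised eigenvalue, = J(w_hat)
    distance: float              # Mahalanobis D, = sqrt(J(w_hat))
    window: TimeWindow | None
    inversion: str

    def __post_init__(self) -> None:
        scale = max(self.criterion, self.eigenvalue, self.distance**2, 1e-300)
        if abs(self.criterion - self.distance**2) > _IDENTITY_RTOL * scale:
            raise AssertionError("J(w_hat) != D^2 beyond tolerance")
        if abs(self.eigenvalue - self.criterion) > _IDENTITY_RTOL * scale:
            raise AssertionError("lambda != J(w_hat) beyond tolerance")


@dataclass
class SeparationTimecourse:
    """Mahalanobis D per sliding-window start."""

    window_starts: np.ndarray
    distance: np.ndarray
    inversion: str
    width: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.window_starts) != len(self.distance):
            raise ValueError("inconsistent time-course lengths")
        if np.any(self.distance < 0):
            raise ValueError("D must be non-negative")


def scatter_matrices(
    vectors: PopulationVectorSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Class means and (unnormalised) within/between scatter matrices.

    Returns (m1, m2, S_W, S_B) with m1 = cat mean, m2 = dog mean,
    computed over the per-image rows of ``vectors``.
    """
    X1 = vectors.class_rows(0)
    X2 = vectors.class_rows(1)
    if len(X1) < 2 or len(X2) < 2:
        raise DegenerateScatterError(
            f"need >= 2 rows per class, got {len(X1)} cat / {len(X2)} dog"
        )
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    C1 = X1 - m1
    C2 = X2 - m2
    S_W = C1.T @ C1 + C2.T @ C2
    d = m2 - m1
    S_B = np.outer(d, d)
    return m1, m2, S_W, S_B


def _invert_apply(S_W: np.ndarray, v: np.ndarray, inversion: str) -> np.ndarray:
    """Compute invert(S_W) @ v under the chosen inversion policy."""
    if inversion not in INVERSIONS:
        raise ValueError(f"inversion must be one of {INVERSIONS}, got {inversion!r}")
    N = S_W.shape[0]
    if inversion == "strict":
        cond = np.linalg.cond(S_W)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            rank = np.linalg.matrix_rank(S_W)
            raise SingularScatterError(
                f"S_W is numerically singular (cond={cond:.3g}, rank {rank}/{N}) "
                "under the 'strict' inversion policy"
            )
        return linalg.solve(S_W, v, assume_a="pos")
    if inversion == "ridge":
        eps = _RIDGE_SCALE * np.trace(S_W) / N
        if eps <= 0:
            eps = _RIDGE_SCALE
        return linalg.solve(S_W + eps * np.eye(N), v, assume_a="pos")
    return np.linalg.pinv(S_W, rcond=_PINV_RTOL) @ v


def lda_direction(
    m1: np.ndarray,
    m2: np.ndarray,
    S_W: np.ndarray,
    inversion: str = "ridge",
) -> np.ndarray:
    """Closed-form Fisher direction w_hat prop S_W^{-1}(m2 - m1).

    Normalised so that w_hat^T S_W w_hat = 1; the sign convention makes
    the dog mean project above the cat mean.
    """
    d = np.asarray(m2, dtype=float) - np.asarray(m1, dtype=float)
    w = _invert_apply(np.asarray(S_W, dtype=float), d, inversion)
    q = float(w @ S_W @ w)
    if q <= 0:
        raise SingularScatterError(
            "w^T S_W w <= 0: scatter too degenerate to normalise the direction"
        )
    w = w / np.sqrt(q)
    if w @ d < 0:
        w = -w
    return w


def mahalanobis_distance(
    m1: np.ndarray,
    m2: np.ndarray,
    S_W: np.ndarray,
    inversion: str = "ridge",
) -> float:
    """D = sqrt((m2 - m1)^T invert(S_W) (m2 - m1)); J(w_hat) = D^2."""
    d = np.asarray(m2, dtype=float) - np.asarray(m1, dtype=float)
    q = float(d @ _invert_apply(np.asarray(S_W, dtype=float), d, inversion))
    if q < 0:
        raise SingularScatterError(
            f"negative Mahalanobis quadratic form ({q:.3g}) under "
            f"inversion={inversion!r}"
        )
    return float(np.sqrt(q))


def fisher_criterion(w: np.ndarray, S_W: np.ndarray, S_B: np.ndarray) -> float:
    """J(w) = (w^T S_B w) / (w^T S_W w)."""
    return float((w @ S_B @ w) / (w @ S_W @ w))


def fisher_separation(
    vectors: PopulationVectorSet, inversion: str = "ridge"
) -> SeparationResult:
    """Full LDA solution for one window's population vectors.

    The criterion, eigenvalue and distance are all computed from the
    quadratic forms (not copied from one another) in the metric the
    inversion policy actually uses — raw S_W for ``strict`` and
    ``pinv``, the Tikhonov-stabilised S_W for ``ridge`` — so the
    J(w_hat) = lambda = D^2 identity is a genuine numerical check.
    """
    m1, m2, S_W, S_B = scatter_matrices(vectors)
    d = m2 - m1
    w_raw = _invert_apply(S_W, d, inversion)
    if inversion == "ridge":
        eps = _RIDGE_SCALE * np.trace(S_W) / S_W.shape[0]
        S_metric = S_W + max(eps, _RIDGE_SCALE) * np.eye(S_W.shape[0])
    else:
        S_metric = S_W
    q = float(w_raw @ S_metric @ w_raw)
    if q <= 0:
        raise SingularScatterError("degenerate scatter: w^T S_W w <= 0")
    w = w_raw / np.sqrt(q)
    if w @ d < 0:
        w = -w
    D2 = float(d @ w_raw)
    if D2 < 0:
        raise SingularScatterError(
            f"negative Mahalanobis quadratic form ({D2:.3g}) under {inversion!r}"
        )
    J = float((w @ S_B @ w) / (w @ S_metric @ w))
    return SeparationResult(
        m1=m1,
        m2=m2,
        S_W=S_W,
        S_B=S_B,
        direction=w,
        criterion=J,
        eigenvalue=float((d @ w) ** 2 / (w @ S_metric @ w)),
        distance=float(np.sqrt(D2)),
        window=vectors.window,
        inversion=inversion,
    )


def project_1d(
    vectors: PopulationVectorSet, direction: np.ndarray
) -> dict[str, dict]:
    """Project per-image vectors onto the LDA axis, grouped by class.

    Returns {"cat": {"values", "mean"}, "dog": {...}}; under the
    w^T S_W w = 1 normalisation the squared gap between the class means
    equals J(w_hat).
    """
    w = np.asarray(direction, dtype=float)
    if w.shape != (vectors.n_neurons,):
        raise ValueError(
            f"direction has shape {w.shape}, expected ({vectors.n_neurons},)"
        )
    if np.all(w == 0):
        raise ValueError("direction is the zero vector")
    out = {}
    for name, label in (("cat", 0), ("dog", 1)):
        vals = vectors.class_rows(label) @ w
        out[name] = {"values": vals, "mean": float(vals.mean())}
    return out


def separation_timecourse(
    datasets: SpikeDataset | list[SpikeDataset],
    windows: list[TimeWindow],
    inversion: str = "ridge",
) -> SeparationTimecourse:
    """Mahalanobis D between category means for each sliding window."""
    if isinstance(datasets, SpikeDataset):
        datasets = [datasets]
    if not windows:
        raise ValueError("no windows given")
    stacks = [population_vector_stack(d, windows) for d in datasets]
    D = np.empty(len(windows))
    provenance: list[str] = []
    for wi in range(len(windows)):
        vs = (
            stacks[0][wi]
            if len(datasets) == 1
            else pool_pseudopopulation([s[wi] for s in stacks])
        )
        if wi == 0:
            provenance = list(vs.provenance)
        m1, m2, S_W, _ = scatter_matrices(vs)
        D[wi] = mahalanobis_distance(m1, m2, S_W, inversion)
    return SeparationTimecourse(
        window_starts=np.array([w.start for w in windows]),
        distance=D,
        inversion=inversion,
        width=windows[0].width,
        provenance=provenance,
    )
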