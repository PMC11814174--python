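"""Statistical comparisons between areas, sessions and time windows.

Three tests, matching the study design:

* paired t on two decoding-accuracy time courses sharing a window grid
  (pre vs post training, TE vs TEO), one- or two-sided;
* Mann-Whitney U on Mahalanobis-distance samples from two ranges of
  sliding-window starts (e.g. 0-100 ms vs 250-350 ms) — exact null
  distribution for small combined n without ties, normal approximation
  with tie correction otherwise;
* two-proportion pooled z-test on responsive-neuron counts.

All p-values are reported raw (no correction across comparisons).  Note
that D samples from overlapping sliding windows are autocorrelated; the
default replicates the windowed-sample procedure as-is, and ``thin``
subsamples every k-th window as a robustness option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .decoding import DecodingTimecourse
from .separation import SeparationTimecourse

_EXACT_MAX_N = 20


@dataclass
class ComparisonReport:
    """Outcome of one statistical comparison, with full context."""

    test: str
    groups: tuple[str, str]
    statistic: float
    p_value: float
    alternative: str
    n: tuple[int, int]
    windows: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if min(self.n) < 1:
            raise ValueError("each group needs n >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["n"] = list(self.n)
        return d


def paired_t_timecourses(
    a: DecodingTimecourse,
    b: DecodingTimecourse,
    alternative: str = "two-sided",
    names: tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """Paired t-test on per-window accuracy differences of two curves.

    The pairing unit is the window start (the only index the curves
    share); grids must be identical.  ``alternative`` follows scipy:
    ``"less"`` tests b > a (a - b < 0), ``"greater"`` tests a > b.
    Zero-variance differences (identical curves) yield p = 1 with a
    ``degenerate`` flag rather than an error.
    """
    if not np.array_equal(a.window_starts, b.window_starts):
        raise ValueError("window grids differ; the curves cannot be paired")
    diffs = a.accuracy - b.accuracy
    flags = ["pairing_unit=window_start"]
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        return ComparisonReport(
            test="paired_t",
            groups=names,
            statistic=0.0,
            p_value=1.0,
            alternative=alternative,
            n=(len(diffs), len(diffs)),
            flags=flags + ["degenerate_zero_variance"],
        )
    res = stats.ttest_rel(a.accuracy, b.accuracy, alternative=alternative)
    return ComparisonReport(
        test="paired_t",
        groups=names,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n=(len(diffs), len(diffs)),
        flags=flags,
        details={"mean_difference": float(diffs.mean())},
    )


def _select_starts(tc: SeparationTimecourse, lo: float, hi: float) -> np.ndarray:
    mask = (tc.window_starts >= lo) & (tc.window_starts <= hi)
    return tc.distance[mask]


def mannwhitney_windows(
    tc: SeparationTimecourse,
    range_a: tuple[float, float],
    range_b: tuple[float, float],
    alternative: str = "two-sided",
    thin: int = 1,
) -> ComparisonReport:
    """Mann-Whitney U on D samples from two window-start ranges.

    Ranges are inclusive on window starts and must not overlap.
    ``alternative="greater"`` tests that range_b distances exceed
    range_a (the within-trial growth contrast).  ``thin`` keeps every
    k-th window in each range, a robustness option against the
    autocorrelation of overlapping windows.
    """
    if not (range_a[1] < range_b[0] or range_b[1] < range_a[0]):
        raise ValueError(f"window-start ranges {range_a} and {range_b} overlap")
    xa = _select_starts(tc, *range_a)[::thin]
    xb = _select_starts(tc, *range_b)[::thin]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("a window-start range selects no windows")
    combined = np.concatenate([xa, xb])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    # U for "is b greater": count pairs where b outranks a
    scipy_alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[
        alternative
    ]
    res = stats.mannwhitneyu(
        xb, xa, alternative=scipy_alt, method=method, use_continuity=True
    )
    return ComparisonReport(
        test="mannwhitney_u",
        groups=(f"starts {range_a[0]}-{range_a[1]} ms", f"starts {range_b[0]}-{range_b[1]} ms"),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        n=(len(xa), len(xb)),
        windows={"range_a": list(range_a), "range_b": list(range_b), "thin": thin},
        flags=(["ties_midrank"] if has_ties else []) + [f"method={method}"],
    )


def proportion_z_test(
    k1: int, n1: int, k2: int, n2: int, names: tuple[str, str] = ("group1", "group2")
) -> ComparisonReport:
    """Two-sided pooled two-proportion z-test (e.g. responsive fractions)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("each group needs n >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    if k1 * n2 == k2 * n1:  # identical proportions -> z = 0 exactly
        z, p = 0.0, 1.0
    else:
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return ComparisonReport(
        test="two_proportion_z",
        groups=names,
        statistic=float(z),
        p_value=float(p),
        alternative="two-sided",
        n=(n1, n2),
        details={"p1": k1 / n1, "p2": k2 / n2, "k": [k1, k2]},
    )


def build_report(runs: list[dict]) -> dict:
    """Assemble a machine-readable study report from completed run dicts.

    Each run dict may carry ``responsiveness`` summaries,
    ``decoding`` / ``separation`` time courses (as plain dicts) and
    ``comparisons`` (:class:`ComparisonReport` or dicts), plus a
    ``config`` block; everything is passed through into a deterministic,
    JSON-serialisable structure with provenance intact.
    """
    if not runs:
        raise ValueError("build_report needs at least one run")
    out_runs = []
    for run in runs:
        r = dict(run)
        if "comparisons" in r:
            r["comparisons"] = [
                c.to_dict() if isinstance(c, ComparisonReport) else c
                for c in r["comparisons"]
            ]
        out_runs.append(r)
    report = {"schema": "popsep-report/1", "runs": out_runs}
    # round-trip through JSON so the result is guaranteed serialisable
    return json.loads(json.dumps(report, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def report_text(report: dict) -> str:
    """Human-readable rendering of a :func:`build_report` structure."""
    lines = [f"popsep study report ({report['schema']})"]
    for run in report["runs"]:
        name = run.get("name", "run")
        lines.append(f"\n== {name} ==")
        if "responsiveness" in run:
            s = run["responsiveness"]
            lines.append(
                f"  responsive neurons: {s['n_responsive']}/{s['n_total']} "
                f"({s['percent_responsive']:.1f}%)"
            )
        for c in run.get("comparisons", []):
            lines.append(
                f"  {c['test']} [{c['groups'][0]} vs {c['groups'][1]}], "
                f"{c['alternative']}: stat={c['statistic']:.4g}, p={c['p_value']:.4g}"
            )
    return "\n".join(lines) + "\n"
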