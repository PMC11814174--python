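"""Config-driven end-to-end runs: simulate/load -> classify -> decode ->
separate -> compare -> report.

A run config (YAML or dict) names one or more *cells* — area x session
combinations backed either by an on-disk dataset or a synthetic
configuration — plus the window grid, decoder settings, inversion
policy, responsiveness windows and the two window-start contrast
ranges.  ``run_pipeline`` executes every stage for every cell, writes
all intermediate artifacts (CSV/JSON) into the run directory and ends
with a study report; everything is deterministic given the config.

One top-level seed expands into named per-stage streams (simulation
seeds live in each cell's synthetic config; the decoder fold stream is
derived from ``decoder.seed``), so stages can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import (
    ComparisonReport,
    build_report,
    mannwhitney_windows,
    paired_t_timecourses,
    proportion_z_test,
    report_text,
)
from .data_model import SpikeDataset, TimeWindow, load_spike_dataset_dir, write_spike_dataset
from .decoding import DecodingTimecourse, decoding_timecourse
from .popvec import sliding_windows
from .responsiveness import classify_neurons, neuron_latencies, summarize_responsiveness
from .separation import INVERSIONS, SeparationTimecourse, separation_timecourse
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("popsep.pipeline")

DEFAULT_CONFIG: dict = {
    "windows": {"start_min": -100.0, "start_max": 300.0, "width": 100.0, "step": 1.0},
    "decoder": {"k": 10, "seed": 0, "reg": 1.0},
    "inversion": "ridge",
    "responsiveness": {
        "baseline": [-200.0, 0.0],
        "stimulus": [0.0, 350.0],
        "alpha": 0.05,
        "family": "per_neuron",
    },
    "contrasts": {"early": [0.0, 100.0], "late": [250.0, 350.0]},
}


class ConfigValidationError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid run config:\n  " + "\n  ".join(errors))


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def validate_config(config: str | Path | dict) -> list[str]:
    """Type- and cross-check a run config; returns a list of errors."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        return ["config: must be a mapping"]
    cfg = _merged(config)
    errors: list[str] = []
    cells = cfg.get("cells")
    if not isinstance(cells, list) or not cells:
        errors.append("cells: at least one cell is required")
        cells = []
    for i, cell in enumerate(cells):
        where = f"cells[{i}]"
        if not isinstance(cell, dict):
            errors.append(f"{where}: must be a mapping")
            continue
        if "name" not in cell:
            errors.append(f"{where}.name: required")
        has_data = "data" in cell
        has_synth = "synthetic" in cell
        if has_data == has_synth:
            errors.append(f"{where}: exactly one of 'data' or 'synthetic' is required")
        if has_data and not Path(cell["data"]).exists():
            errors.append(f"{where}.data: path {cell['data']!r} does not exist")
        if has_synth:
            try:
                SyntheticConfig.from_dict(cell["synthetic"])
            except (TypeError, ValueError) as e:
                errors.append(f"{where}.synthetic: {e}")
    w = cfg["windows"]
    for key in ("start_min", "start_max", "width", "step"):
        if not isinstance(w.get(key), (int, float)):
            errors.append(f"windows.{key}: must be a number")
    if all(isinstance(w.get(k), (int, float)) for k in ("start_min", "start_max", "width", "step")):
        if w["width"] <= 0:
            errors.append(f"windows.width: must be > 0, got {w['width']}")
        if w["step"] <= 0:
            errors.append(f"windows.step: must be > 0, got {w['step']}")
        if w["start_min"] > w["start_max"]:
            errors.append("windows: start_min must be <= start_max")
        for name in ("early", "late"):
            rng = cfg["contrasts"].get(name)
            if (
                not isinstance(rng, (list, tuple))
                or len(rng) != 2
                or not all(isinstance(x, (int, float)) for x in rng)
            ):
                errors.append(f"contrasts.{name}: must be [lo, hi]")
            elif rng[0] > rng[1]:
                errors.append(f"contrasts.{name}: lo > hi in {list(rng)}")
            elif rng[0] < w["start_min"] or rng[1] > w["start_max"]:
                errors.append(
                    f"contrasts.{name}: range {list(rng)} outside window-start grid "
                    f"[{w['start_min']}, {w['start_max']}]"
                )
    d = cfg["decoder"]
    if not isinstance(d.get("k"), int) or d.get("k", 0) < 2:
        errors.append("decoder.k: must be an integer >= 2")
    if cfg["inversion"] not in INVERSIONS:
        errors.append(f"inversion: must be one of {INVERSIONS}, got {cfg['inversion']!r}")
    r = cfg["responsiveness"]
    for key in ("baseline", "stimulus"):
        rng = r.get(key)
        if not isinstance(rng, (list, tuple)) or len(rng) != 2 or rng[0] >= rng[1]:
            errors.append(f"responsiveness.{key}: must be [lo, hi] with lo < hi")
    alpha = r.get("alpha")
    if not isinstance(alpha, (int, float)) or not 0 < alpha < 1:
        errors.append("responsiveness.alpha: must lie in (0, 1)")
    return errors


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _get_dataset(cell: dict, cell_dir: Path) -> SpikeDataset:
    if "data" in cell:
        return load_spike_dataset_dir(cell["data"])
    sc = SyntheticConfig.from_dict(cell["synthetic"])
    data_dir = cell_dir / "data"
    dataset = generate_dataset(sc)
    write_spike_dataset(dataset, data_dir)
    return dataset


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Execute all stages for every cell and write the study report.

    Returns the run directory.  Any stage failure raises with the stage
    name and cell attached.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    errors = validate_config(config)
    if errors:
        raise ConfigValidationError(errors)
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    w = cfg["windows"]
    windows = sliding_windows(w["start_min"], w["start_max"], w["width"], w["step"])
    rcfg = cfg["responsiveness"]
    baseline = TimeWindow(rcfg["baseline"][0], rcfg["baseline"][1] - rcfg["baseline"][0])
    stimulus = TimeWindow(rcfg["stimulus"][0], rcfg["stimulus"][1] - rcfg["stimulus"][0])
    dcfg = cfg["decoder"]
    reg = dcfg.get("reg")

    runs: list[dict] = []
    courses: dict[str, DecodingTimecourse] = {}
    seps: dict[str, SeparationTimecourse] = {}
    summaries: dict[str, dict] = {}
    meta: dict[str, dict] = {}
    for cell in cfg["cells"]:
        name = cell["name"]
        cell_dir = out / "cells" / name
        cell_dir.mkdir(parents=True, exist_ok=True)
        stage = "simulate/load"
        try:
            t0 = time.perf_counter()
            dataset = _get_dataset(cell, cell_dir)
            log.info("cell %s: %s done in %.2fs", name, stage, time.perf_counter() - t0)

            stage = "classify"
            t0 = time.perf_counter()
            table = classify_neurons(
                dataset, baseline, stimulus, alpha=rcfg["alpha"], family=rcfg["family"]
            )
            summary = summarize_responsiveness([table])
            is_dog = np.array(
                [dataset.category_of(i) == "dog" for i in dataset.image_ids]
            )
            sig = table.significant.to_numpy()
            pd.DataFrame(
                {
                    "class": table.classes,
                    "n_sig_dog": (sig & is_dog).sum(axis=1),
                    "n_sig_cat": (sig & ~is_dog).sum(axis=1),
                    "latency_ms": neuron_latencies(dataset, baseline),
                }
            ).to_csv(cell_dir / "responsiveness.csv", index_label="neuron_id")
            log.info("cell %s: classify done in %.2fs", name, time.perf_counter() - t0)

            stage = "decode"
            t0 = time.perf_counter()
            tc = decoding_timecourse(
                dataset, windows, k=dcfg["k"], seed=dcfg["seed"], reg=reg
            )
            dec_df = pd.DataFrame(
                {"window_start_ms": tc.window_starts, "mean_accuracy": tc.accuracy}
            )
            for f in range(tc.k):
                dec_df[f"fold_{f + 1}"] = tc.fold_accuracies[:, f]
            dec_df.to_csv(cell_dir / "decoding.csv", index=False)
            log.info("cell %s: decode done in %.2fs", name, time.perf_counter() - t0)

            stage = "separate"
            t0 = time.perf_counter()
            sep = separation_timecourse(dataset, windows, inversion=cfg["inversion"])
            pd.DataFrame(
                {"window_start_ms": sep.window_starts, "mahalanobis_D": sep.distance}
            ).to_csv(cell_dir / "separation.csv", index=False)
            log.info("cell %s: separate done in %.2fs", name, time.perf_counter() - t0)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed for cell {name!r}: {e}") from e

        courses[name] = tc
        seps[name] = sep
        summaries[name] = summary
        meta[name] = {"area": dataset.area, "session": dataset.session}
        runs.append(
            {
                "name": name,
                "area": dataset.area,
                "session": dataset.session,
                "monkey_id": dataset.monkey_id,
                "n_neurons": dataset.n_neurons,
                "n_images": len(dataset.stimuli),
                "responsiveness": summary,
                "latency_rule": "baseline_threshold(3sd, 20ms)",
            }
        )

    comparisons: list[ComparisonReport] = []
    early = tuple(cfg["contrasts"]["early"])
    late = tuple(cfg["contrasts"]["late"])
    for name, sep in seps.items():
        comparisons.append(
            mannwhitney_windows(sep, early, late, alternative="greater")
        )
        comparisons[-1].details["cell"] = name
    names = list(courses)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ma, mb = meta[a], meta[b]
            same_area = ma["area"] == mb["area"]
            same_session = ma["session"] == mb["session"]
            if same_area != same_session:  # pre-vs-post or TE-vs-TEO
                comparisons.append(
                    paired_t_timecourses(
                        courses[a], courses[b], alternative="less", names=(a, b)
                    )
                )
                if same_area:  # pre vs post: also compare responsive proportions
                    comparisons.append(
                        proportion_z_test(
                            summaries[a]["n_responsive"],
                            summaries[a]["n_total"],
                            summaries[b]["n_responsive"],
                            summaries[b]["n_total"],
                            names=(a, b),
                        )
                    )

    report = build_report(
        [
            {
                **run,
                "comparisons": [
                    c for c in comparisons if run["name"] in (list(c.groups) + [c.details.get("cell")])
                ],
                "config": {
                    "windows": cfg["windows"],
                    "decoder": cfg["decoder"],
                    "inversion": cfg["inversion"],
                    "responsiveness": cfg["responsiveness"],
                    "contrasts": cfg["contrasts"],
                    "cell": cfg["cells"][[r["name"] for r in runs].index(run["name"])],
                },
                "config_hash": _config_hash(cfg),
            }
            for run in runs
        ]
    )
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (out / "report.txt").write_text(report_text(report))
    return out
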