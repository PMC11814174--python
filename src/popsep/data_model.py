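"""Domain types for trial-aligned extracellular spike recordings.

The shared vocabulary of the package: stimulus images labelled cat/dog,
per-presentation spike trains, and the dataset container that every
analysis stage consumes.  Times are in milliseconds relative to stimulus
onset (0 = onset) and all analysis windows are half-open ``[t, t + dt)``
so that a spike on a window edge is counted exactly once.

Datasets serialize to three plain CSV tables plus a YAML metadata file
(see :func:`write_spike_dataset`); loading validates every referential
and range invariant and raises instead of silently repairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CATEGORIES = ("cat", "dog")

STIMULI_FILE = "stimuli.csv"
TRIALS_FILE = "trials.csv"
SPIKES_FILE = "spikes.csv"
META_FILE = "meta.yaml"


class FormatError(ValueError):
    """A tabular file does not conform to the expected dialect."""


class ReferentialIntegrityError(ValueError):
    """A record references an id that does not exist."""


class ValidationError(ValueError):
    """A dataset invariant is violated."""


@dataclass(frozen=True)
class StimulusImage:
    """One stimulus picture with its binary category label."""

    image_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"image {self.image_id!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window ``[start, start + width)`` in ms."""

    start: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError(f"window width must be > 0, got {self.width}")

    @property
    def end(self) -> float:
        return self.start + self.width

    @property
    def width_s(self) -> float:
        """Window width in seconds (rates are reported in spikes/s)."""
        return self.width / 1000.0


@dataclass
class TrialRecord:
    """A single stimulus presentation with per-neuron spike times (ms)."""

    trial_id: str
    image_id: str
    presentation_duration: float
    spike_times: dict[str, np.ndarray]

    def n_spikes(self) -> int:
        return int(sum(len(v) for v in self.spike_times.values()))


@dataclass
class SpikeDataset:
    """Trial-aligned spike data for one area x session x monkey cell.

    Parameters
    ----------
    area, session, monkey_id
        Recording metadata. ``area`` is ``"TEO"`` or ``"TE"``; ``session``
        is ``"pre"`` or ``"post"`` (relative to category training).
    neuron_ids
        Ordered neuron identifiers; every trial carries a spike list
        (possibly empty) for each.
    stimuli
        The stimulus set; image ids must be unique.
    trials
        One record per presentation.
    analysis_window
        ``(start, end)`` in ms; all spike times must lie inside.
    """

    area: str
    session: str
    monkey_id: str
    neuron_ids: list[str]
    stimuli: list[StimulusImage]
    trials: list[TrialRecord]
    analysis_window: tuple[float, float] = (-300.0, 400.0)
    dataset_id: str = ""
    _flat_cache: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.dataset_id:
            self.dataset_id = f"{self.monkey_id}_{self.area}_{self.session}"
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.area not in ("TEO", "TE"):
            raise ValidationError(f"area must be TEO or TE, got {self.area!r}")
        if self.session not in ("pre", "post"):
            raise ValidationError(f"session must be pre or post, got {self.session!r}")
        lo, hi = self.analysis_window
        if not lo < hi:
            raise ValidationError(f"analysis_window {self.analysis_window} is empty")
        ids = [s.image_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate image_ids: {dupes}")
        image_set = set(ids)
        neuron_set = set(self.neuron_ids)
        trial_ids = set()
        trials_per_image: dict[str, int] = {i: 0 for i in ids}
        offenders: list[str] = []
        for tr in self.trials:
            if tr.trial_id in trial_ids:
                raise ValidationError(f"duplicate trial_id {tr.trial_id!r}")
            trial_ids.add(tr.trial_id)
            if tr.image_id not in image_set:
                raise ReferentialIntegrityError(
                    f"trial {tr.trial_id!r} references unknown image {tr.image_id!r}"
                )
            trials_per_image[tr.image_id] += 1
            if set(tr.spike_times) != neuron_set:
                missing = sorted(neuron_set - set(tr.spike_times))
                extra = sorted(set(tr.spike_times) - neuron_set)
                raise ReferentialIntegrityError(
                    f"trial {tr.trial_id!r}: spike map neurons do not match dataset "
                    f"neuron_ids (missing {missing}, unknown {extra})"
                )
            for nid, st in tr.spike_times.items():
                st = np.asarray(st, dtype=float)
                tr.spike_times[nid] = st
                if st.size:
                    if np.any((st < lo) | (st > hi)):
                        bad = st[(st < lo) | (st > hi)]
                        offenders.append(
                            f"trial {tr.trial_id!r} neuron {nid!r}: {bad.tolist()}"
                        )
                    if np.any(np.diff(st) <= 0):
                        raise ValidationError(
                            f"trial {tr.trial_id!r} neuron {nid!r}: spike times must "
                            "be strictly increasing"
                        )
        if offenders:
            raise ValidationError(
                "spike times outside analysis_window "
                f"{self.analysis_window}: " + "; ".join(offenders)
            )
        if self.trials:
            empty = [i for i, n in trials_per_image.items() if n == 0]
            if empty:
                raise ValidationError(f"images with zero trials: {sorted(empty)}")
        self._flat_cache = None

    # -- convenience -----------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def image_ids(self) -> list[str]:
        return [s.image_id for s in self.stimuli]

    def category_of(self, image_id: str) -> str:
        for s in self.stimuli:
            if s.image_id == image_id:
                return s.category
        raise KeyError(f"unknown image_id {image_id!r}")

    def trials_for_image(self, image_id: str) -> list[TrialRecord]:
        """All presentations of one image, in dataset order."""
        if image_id not in set(self.image_ids):
            raise KeyError(f"unknown image_id {image_id!r}")
        return [t for t in self.trials if t.image_id == image_id]

    def flat_spikes(self) -> dict[str, np.ndarray]:
        """Flattened spike arrays for vectorised windowed counting.

        Returns arrays ``time`` (ms), ``trial_idx``, ``neuron_idx``,
        ``image_idx`` (one entry per spike, time-sorted), plus
        ``trial_image_idx`` and ``trials_per_image`` lookup arrays.
        Cached; treat as read-only.
        """
        if self._flat_cache is None:
            n_index = {n: j for j, n in enumerate(self.neuron_ids)}
            i_index = {im: j for j, im in enumerate(self.image_ids)}
            times, t_idx, n_idx = [], [], []
            trial_image = np.empty(len(self.trials), dtype=np.intp)
            for ti, tr in enumerate(self.trials):
                trial_image[ti] = i_index[tr.image_id]
                for nid, st in tr.spike_times.items():
                    if len(st):
                        times.append(np.asarray(st, dtype=float))
                        t_idx.append(np.full(len(st), ti, dtype=np.intp))
                        n_idx.append(np.full(len(st), n_index[nid], dtype=np.intp))
            if times:
                time = np.concatenate(times)
                trial_idx = np.concatenate(t_idx)
                neuron_idx = np.concatenate(n_idx)
            else:
                time = np.empty(0)
                trial_idx = np.empty(0, dtype=np.intp)
                neuron_idx = np.empty(0, dtype=np.intp)
            order = np.argsort(time, kind="stable")
            time, trial_idx, neuron_idx = time[order], trial_idx[order], neuron_idx[order]
            self._flat_cache = {
                "time": time,
                "trial_idx": trial_idx,
                "neuron_idx": neuron_idx,
                "image_idx": trial_image[trial_idx] if len(time) else np.empty(0, dtype=np.intp),
                "trial_image_idx": trial_image,
                "trials_per_image": np.bincount(trial_image, minlength=len(self.stimuli)),
            }
        return self._flat_cache


def trials_for_image(dataset: SpikeDataset, image_id: str) -> list[TrialRecord]:
    """Module-level alias for :meth:`SpikeDataset.trials_for_image`."""
    return dataset.trials_for_image(image_id)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")


def load_spike_dataset(
    spikes_path: str | Path,
    trials_path: str | Path,
    stimuli_path: str | Path,
    meta: str | Path | Mapping,
) -> SpikeDataset:
    """Load a dataset from the three CSV tables and YAML metadata.

    ``stimuli.csv``: image_id,category.  ``trials.csv``:
    trial_id,image_id,presentation_duration_ms.  ``spikes.csv`` (long):
    trial_id,neuron_id,spike_time_ms.  ``meta`` may be a path to a YAML
    file or an already-parsed mapping with keys area, session, monkey_id,
    neuron_ids, analysis_window.
    """
    for p in (spikes_path, trials_path, stimuli_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    if isinstance(meta, (str, Path)):
        with open(meta) as fh:
            meta = yaml.safe_load(fh)
    for key in ("area", "session", "monkey_id", "neuron_ids", "analysis_window"):
        if key not in meta:
            raise FormatError(f"meta: missing required key {key!r}")

    stim_df = pd.read_csv(stimuli_path, dtype=str)
    _require_columns(stim_df, ["image_id", "category"], "stimuli")
    stimuli = [StimulusImage(r.image_id, r.category) for r in stim_df.itertuples()]

    trials_df = pd.read_csv(
        trials_path, dtype={"trial_id": str, "image_id": str},
        float_precision="round_trip",
    )
    _require_columns(
        trials_df, ["trial_id", "image_id", "presentation_duration_ms"], "trials"
    )

    spikes_df = pd.read_csv(
        spikes_path, dtype={"trial_id": str, "neuron_id": str},
        float_precision="round_trip",
    )
    _require_columns(spikes_df, ["trial_id", "neuron_id", "spike_time_ms"], "spikes")

    neuron_ids = [str(n) for n in meta["neuron_ids"]]
    neuron_set = set(neuron_ids)
    trial_set = set(trials_df["trial_id"])
    unknown_neurons = sorted(set(spikes_df["neuron_id"]) - neuron_set)
    if unknown_neurons:
        raise ReferentialIntegrityError(
            f"spikes reference neuron_id(s) absent from meta: {unknown_neurons}"
        )
    unknown_trials = sorted(set(spikes_df["trial_id"]) - trial_set)
    if unknown_trials:
        raise ReferentialIntegrityError(
            f"spikes reference unknown trial_id(s): {unknown_trials}"
        )

    by_trial: dict[str, dict[str, list[float]]] = {}
    for tid, nid, t in zip(
        spikes_df["trial_id"], spikes_df["neuron_id"], spikes_df["spike_time_ms"]
    ):
        by_trial.setdefault(tid, {}).setdefault(nid, []).append(float(t))

    trials = []
    for r in trials_df.itertuples():
        spike_map = {
            nid: np.sort(np.asarray(by_trial.get(r.trial_id, {}).get(nid, []), dtype=float))
            for nid in neuron_ids
        }
        trials.append(
            TrialRecord(
                trial_id=r.trial_id,
                image_id=r.image_id,
                presentation_duration=float(r.presentation_duration_ms),
                spike_times=spike_map,
            )
        )

    window = tuple(float(x) for x in meta["analysis_window"])
    return SpikeDataset(
        area=str(meta["area"]),
        session=str(meta["session"]),
        monkey_id=str(meta["monkey_id"]),
        neuron_ids=neuron_ids,
        stimuli=stimuli,
        trials=trials,
        analysis_window=window,  # type: ignore[arg-type]
        dataset_id=str(meta.get("dataset_id", "")),
    )


def load_spike_dataset_dir(data_dir: str | Path) -> SpikeDataset:
    """Load a dataset from a directory holding the four standard files."""
    d = Path(data_dir)
    return load_spike_dataset(
        d / SPIKES_FILE, d / TRIALS_FILE, d / STIMULI_FILE, d / META_FILE
    )


def write_spike_dataset(dataset: SpikeDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three CSV tables plus meta.yaml; round-trips exactly.

    Spike times are written with repr-precision so that load(write(d)) == d
    field-by-field and write(load(write(d))) is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stimuli": out / STIMULI_FILE,
        "trials": out / TRIALS_FILE,
        "spikes": out / SPIKES_FILE,
        "meta": out / META_FILE,
    }
    stim_df = pd.DataFrame(
        {"image_id": dataset.image_ids, "category": [s.category for s in dataset.stimuli]}
    )
    stim_df.to_csv(paths["stimuli"], index=False)

    trows = [
        (t.trial_id, t.image_id, repr(t.presentation_duration)) for t in dataset.trials
    ]
    pd.DataFrame(
        trows, columns=["trial_id", "image_id", "presentation_duration_ms"]
    ).to_csv(paths["trials"], index=False)

    with open(paths["spikes"], "w") as fh:
        fh.write("trial_id,neuron_id,spike_time_ms\n")
        for tr in dataset.trials:
            for nid in dataset.neuron_ids:
                for t in tr.spike_times[nid]:
                    fh.write(f"{tr.trial_id},{nid},{float(t)!r}\n")

    meta = {
        "area": dataset.area,
        "session": dataset.session,
        "monkey_id": dataset.monkey_id,
        "dataset_id": dataset.dataset_id,
        "neuron_ids": list(dataset.neuron_ids),
        "analysis_window": [float(x) for x in dataset.analysis_window],
    }
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths
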