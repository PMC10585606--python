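"""Data model, file I/O, epoching and configuration.

The on-disk formats are plain tab-separated text:

``samples.tsv``
    run_id, sample_index, timestamp_ms, pupil, gaze_x, gaze_y, blink.
    ``gaze_x``/``gaze_y`` and ``blink`` are optional; the pupil column is
    mandatory.  One row per eye-tracker sample at a fixed rate
    (500 samples/s by default).

``events.tsv``
    run_id, trial_index, onset_sample, trial_type, reward, contrast,
    spatial_frequency, response, reaction_time.  ``contrast`` and
    ``spatial_frequency`` are present iff ``trial_type == "stim"``; empty
    strings encode absent fields.

Sample indexing is 0-based and trial windows are half-open
``[onset, onset + trial_samples)``, so epoching is a pure slice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConsistencyError,
    EpochingError,
    FormatError,
    ParameterError,
    SamplingError,
)

logger = logging.getLogger("pupilamp")

SAMPLE_COLUMNS = ("run_id", "sample_index", "timestamp_ms", "pupil")
OPTIONAL_SAMPLE_COLUMNS = ("gaze_x", "gaze_y", "blink")
EVENT_COLUMNS = (
    "run_id",
    "trial_index",
    "onset_sample",
    "trial_type",
    "reward",
    "contrast",
    "spatial_frequency",
    "response",
    "reaction_time",
)
TRIAL_TYPES = ("stim", "null")
REWARD_LEVELS = ("high", "low")
RESPONSES = ("correct", "incorrect", "missed")


@dataclass
class SampleSeries:
    """Continuous eye-tracker record for one run.

    ``pupil`` is in arbitrary tracker units on input and in z-units after
    preprocessing.  ``blink`` flags samples the tracker marked as inside a
    blink; the pupil value there is unusable (typically 0).
    """

    run_id: str
    pupil: np.ndarray
    timestamp_ms: np.ndarray | None = None
    gaze_x: np.ndarray | None = None
    gaze_y: np.ndarray | None = None
    blink: np.ndarray | None = None
    rate: float = 500.0

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.timestamp_ms is not None:
            self.timestamp_ms = np.asarray(self.timestamp_ms, dtype=float)
        if self.blink is not None:
            self.blink = np.asarray(self.blink, dtype=bool)
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.pupil.size

    @property
    def has_gaze(self) -> bool:
        return self.gaze_x is not None and self.gaze_y is not None

    def blink_mask(self) -> np.ndarray:
        if self.blink is None:
            return np.zeros(self.n_samples, dtype=bool)
        return self.blink

    def validate(self, rtol: float = 1e-6) -> None:
        """Check length agreement and timestamp uniformity."""
        for name in ("timestamp_ms", "gaze_x", "gaze_y", "blink"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != self.n_samples:
                raise FormatError(
                    f"run {self.run_id!r}: column {name} has length "
                    f"{len(arr)} != {self.n_samples}"
                )
        if self.timestamp_ms is not None and self.n_samples > 1:
            step = 1000.0 / self.rate
            diffs = np.diff(self.timestamp_ms)
            if np.any(diffs <= 0) or not np.allclose(diffs, step, rtol=rtol, atol=step * rtol):
                raise SamplingError(
                    f"run {self.run_id!r}: timestamps not uniform at "
                    f"{step:.3f} ms"
                )

    def replace(self, **changes) -> "SampleSeries":
        return dataclasses.replace(self, **changes)


@dataclass
class TrialMatrix:
    """Epoched trials-by-samples matrix, row-aligned with its metadata."""

    data: np.ndarray  # (n_trials, n_samples), preprocessed pupil in z-units
    meta: pd.DataFrame  # one row per trial, same order as ``data``

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("trial matrix must be 2-D")
        if len(self.meta) != self.data.shape[0]:
            raise ConsistencyError(
                f"metadata rows ({len(self.meta)}) != trial rows "
                f"({self.data.shape[0]})"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis chain.

    Defaults follow the recording and filtering setup the pipeline was
    designed around: 500 Hz sampling, 15-s trials analyzed over their
    first 7500 samples, a 3rd-order 4 Hz low-pass Butterworth run
    forward and backward over series padded with 200 points fitted from
    the nearest 50 samples, blink intervals padded by 3 samples.
    """

    rate: float = 500.0
    trial_samples: int = 7500
    lowpass_hz: float = 4.0
    filter_order: int = 3
    pad_points: int = 200
    pad_fit_points: int = 50
    blink_pad: int = 3
    n_boot: int = 10000
    alpha: float = 0.05
    rng_seed: int = 0
    # Order-of-operations switches (see docs/methods.md):
    zscore_before_interpolation: bool = False
    filter_scope: str = "run"  # "run" or "concatenated"

    def validate(self) -> None:
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.lowpass_hz >= self.rate / 2:
            raise ParameterError("lowpass_hz must be below the Nyquist rate")
        if self.pad_fit_points > self.pad_points:
            raise ParameterError("pad_fit_points must be <= pad_points")
        for name in ("trial_samples", "filter_order", "pad_points",
                     "pad_fit_points", "n_boot"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.blink_pad < 0:
            raise ParameterError("blink_pad must be >= 0")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.filter_scope not in ("run", "concatenated"):
            raise ParameterError("filter_scope must be 'run' or 'concatenated'")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.asdict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV with exact float round-trip and only '' treated as NA.

    The default NA sentinels would swallow the literal trial type
    ``"null"``.
    """
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""], float_precision="round_trip")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_samples(path: str | Path, rate: float = 500.0) -> dict[str, SampleSeries]:
    """Read a samples.tsv file into one :class:`SampleSeries` per run."""
    df = _read_tsv(path)
    _require_columns(df, SAMPLE_COLUMNS, f"samples file {path}")
    has_gaze = "gaze_x" in df.columns and "gaze_y" in df.columns
    if not has_gaze:
        logger.warning("samples file %s has no gaze columns; gaze analyses "
                       "will be skipped", path)
    series_by_run: dict[str, SampleSeries] = {}
    for run_id, grp in df.groupby("run_id", sort=False):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ConsistencyError(
                f"run {run_id!r}: sample_index is not 0..n-1 contiguous")
        series = SampleSeries(
            run_id=str(run_id),
            pupil=grp["pupil"].to_numpy(dtype=float),
            timestamp_ms=grp["timestamp_ms"].to_numpy(dtype=float),
            gaze_x=grp["gaze_x"].to_numpy(dtype=float) if has_gaze else None,
            gaze_y=grp["gaze_y"].to_numpy(dtype=float) if has_gaze else None,
            blink=(grp["blink"].to_numpy().astype(bool)
                   if "blink" in grp.columns else None),
            rate=rate,
        )
        series.validate()
        series_by_run[str(run_id)] = series
        logger.info("run %s: %d samples", run_id, series.n_samples)
    return series_by_run


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events.tsv trial table; validates levels and reward constancy."""
    df = _read_tsv(path)
    if df.empty:
        logger.warning("events file %s is empty", path)
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    _require_columns(df, [c for c in EVENT_COLUMNS
                          if c not in ("response", "reaction_time")],
                     f"events file {path}")
    df = df.copy()
    df["run_id"] = df["run_id"].astype(str)
    bad_type = ~df["trial_type"].isin(TRIAL_TYPES)
    if bad_type.any():
        raise FormatError(
            f"events: unknown trial_type values "
            f"{sorted(df.loc[bad_type, 'trial_type'].unique())}")
    bad_reward = ~df["reward"].isin(REWARD_LEVELS)
    if bad_reward.any():
        raise FormatError(
            f"events: unknown reward values "
            f"{sorted(df.loc[bad_reward, 'reward'].unique())}")
    if (df.groupby("run_id")["reward"].nunique() > 1).any():
        raise ConsistencyError("reward level must be constant within a run")
    is_stim = df["trial_type"] == "stim"
    if df.loc[is_stim, ["contrast", "spatial_frequency"]].isna().any().any():
        raise ConsistencyError("stim trials must have contrast and "
                               "spatial_frequency")
    if df.loc[~is_stim, ["contrast", "spatial_frequency"]].notna().any().any():
        raise ConsistencyError("null trials must not carry contrast or "
                               "spatial_frequency")
    return df


def read_session(samples_path: str | Path, events_path: str | Path,
                 rate: float = 500.0) -> tuple[dict[str, SampleSeries], pd.DataFrame]:
    """Read and cross-validate one session (one participant's recording).

    Raises :class:`ConsistencyError` when events reference runs absent from
    the samples file or onsets beyond the recorded run.
    """
    series_by_run = read_samples(samples_path, rate=rate)
    events = read_events(events_path)
    missing_runs = set(events["run_id"]) - set(series_by_run)
    if missing_runs:
        raise ConsistencyError(
            f"events reference runs absent from samples: {sorted(missing_runs)}")
    for _, row in events.iterrows():
        n = series_by_run[row["run_id"]].n_samples
        if not 0 <= row["onset_sample"] < n:
            raise ConsistencyError(
                f"trial {row['trial_index']} of run {row['run_id']!r}: onset "
                f"{row['onset_sample']} outside run of {n} samples")
    for trial_type in TRIAL_TYPES:
        logger.info("%d %s trials", int((events["trial_type"] == trial_type).sum()),
                    trial_type)
    return series_by_run, events


def write_samples(series_by_run: Mapping[str, SampleSeries],
                  path: str | Path) -> None:
    frames = []
    for run_id, s in series_by_run.items():
        n = s.n_samples
        frame = {"run_id": run_id,
                 "sample_index": np.arange(n),
                 "timestamp_ms": (s.timestamp_ms if s.timestamp_ms is not None
                                  else np.arange(n) * 1000.0 / s.rate),
                 "pupil": s.pupil}
        if s.has_gaze:
            frame["gaze_x"] = s.gaze_x
            frame["gaze_y"] = s.gaze_y
        frame["blink"] = s.blink_mask().astype(int)
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_trials(series_by_run: Mapping[str, SampleSeries],
                 events: pd.DataFrame,
                 trial_samples: int = 7500,
                 source: str = "pupil") -> TrialMatrix:
    """Slice fixed-length trial windows out of per-run series.

    Row ``i`` of the returned matrix is samples
    ``[onset_i, onset_i + trial_samples)`` of trial ``i``'s run, in the
    order of ``events``.  The fixed window (7500 samples = 15 s at 500
    samples/s by default) is the minimal trial length the design
    guarantees, so all trials become directly comparable.
    """
    if trial_samples <= 0:
        raise ParameterError("trial_samples must be positive")
    rows = np.empty((len(events), trial_samples), dtype=float)
    for i, (_, ev) in enumerate(events.iterrows()):
        series = series_by_run[ev["run_id"]]
        onset = int(ev["onset_sample"])
        stop = onset + trial_samples
        if stop > series.n_samples:
            raise EpochingError(
                f"trial {ev['trial_index']} of run {ev['run_id']!r}: needs "
                f"samples [{onset}, {stop}) but run has {series.n_samples}")
        rows[i] = getattr(series, source)[onset:stop]
    return TrialMatrix(data=rows, meta=events.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(amplitudes: pd.DataFrame,
                  condition_means: pd.DataFrame,
                  tests: pd.DataFrame,
                  bootstrap_summary: dict | None,
                  out_dir: str | Path,
                  config: AnalysisConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write the analysis outputs plus a machine-readable run manifest.

    Emits ``amplitudes.tsv``, ``condition_means.tsv``, ``stats.tsv``,
    ``bootstrap_summary.json`` (if a bootstrap was run) and
    ``manifest.json`` holding the configuration, seed, package versions
    and a sha256 per output file.  Tables are written at full float
    precision so a read-back reproduces every value exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (("amplitudes.tsv", amplitudes),
                     ("condition_means.tsv", condition_means),
                     ("stats.tsv", tests)):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        files[name] = _sha256(path)
    if bootstrap_summary is not None:
        path = out / "bootstrap_summary.json"
        path.write_text(json.dumps(bootstrap_summary, indent=2, sort_keys=True))
        files["bootstrap_summary.json"] = _sha256(path)
    import numpy
    import pandas
    import scipy
    manifest = {
        "config": config.asdict() if config is not None else None,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
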