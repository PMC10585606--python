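"""Pupil preprocessing: blink excision, z-scoring, zero-phase filtering.

The chain applied by :func:`preprocess_session`, in order:

1. blink detection — flagged samples plus any sample with a non-finite
   or non-positive pupil value, each interval padded by 3 samples on
   both sides and merged;
2. linear interpolation across the padded blink intervals;
3. z-scoring of the pupil series concatenated across all runs of the
   session (population SD), so every run shares one global scale;
4. per-run zero-phase low-pass filtering: each run is lengthened by 200
   points at both ends lying on a least-squares line fitted to the
   nearest 50 original samples, run through a 3rd-order 4 Hz digital
   Butterworth filter, reversed and run through the same filter again,
   then restored to original orientation with the pads trimmed.  The two
   passes cancel the filter's phase shift and square its magnitude
   response (half-power at the cutoff).

Interpolating before z-scoring keeps blink artifacts out of the global
mean and SD; both orderings are available via
``AnalysisConfig.zscore_before_interpolation``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.signal

from .core_io import AnalysisConfig, SampleSeries, epoch_trials
from .errors import NormalizationError, ParameterError

logger = logging.getLogger("pupilamp")


@dataclass(frozen=True)
class BlinkInterval:
    """Half-open, already padded blink span within one run."""

    run_id: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ParameterError("blink interval must have start < end")


# ---------------------------------------------------------------------------
# Blink handling
# ---------------------------------------------------------------------------

def detect_blinks(series: SampleSeries, blink_pad: int = 3) -> list[BlinkInterval]:
    """Find padded, merged blink intervals in one run.

    A sample is blink-like when the tracker flagged it *or* its pupil
    value is non-finite or <= 0 (dropout conventions of ASC-derived
    exports).  Each maximal run of blink-like samples is extended by
    ``blink_pad`` samples on both sides, clipped to the run bounds, and
    overlapping intervals are merged.
    """
    mask = series.blink_mask() | ~np.isfinite(series.pupil) | (series.pupil <= 0)
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    starts, ends = edges[::2], edges[1::2]
    starts = np.maximum(starts - blink_pad, 0)
    ends = np.minimum(ends + blink_pad, series.n_samples)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return [BlinkInterval(series.run_id, s, e) for s, e in merged]


def interpolate_blinks(series: SampleSeries,
                       intervals: list[BlinkInterval]) -> SampleSeries:
    """Replace blink intervals with the line joining their flanking samples.

    Samples outside the (padded) intervals are untouched.  An interval
    touching the run start or end has no flank on that side; the nearest
    finite value is held flat instead and a warning is logged.
    """
    pupil = series.pupil.copy()
    n = pupil.size
    for iv in intervals:
        s, e = iv.start_sample, iv.end_sample
        left = pupil[s - 1] if s > 0 else None
        right = pupil[e] if e < n else None
        if left is None and right is None:
            logger.warning("run %s: blink covers the whole run; cannot "
                           "interpolate", series.run_id)
            continue
        if left is None or right is None:
            held = right if left is None else left
            pupil[s:e] = held
            logger.warning("run %s: blink [%d, %d) touches the run edge; "
                           "held value %.6g", series.run_id, s, e, held)
            continue
        gap = e - s
        steps = np.arange(1, gap + 1, dtype=float)
        pupil[s:e] = left + steps * (right - left) / (gap + 1)
    return series.replace(pupil=pupil)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def zscore_series(series_by_run: Mapping[str, SampleSeries]
                  ) -> tuple[dict[str, SampleSeries], float, float]:
    """Z-score the pupil series concatenated across all runs.

    One global affine map ``(x - mean) / sd`` (population SD over the
    concatenation) is applied to every run, so per-run segments keep
    their relative scale.  Returns the transformed runs plus the mean
    and SD used.
    """
    concatenated = np.concatenate([s.pupil for s in series_by_run.values()])
    if concatenated.size < 2:
        raise NormalizationError("need at least 2 samples to z-score")
    mean = float(concatenated.mean())
    sd = float(concatenated.std())  # population (1/N) SD
    if sd == 0.0 or not np.isfinite(sd):
        raise NormalizationError("zero or undefined variance; cannot z-score")
    out = {run_id: s.replace(pupil=(s.pupil - mean) / sd)
           for run_id, s in series_by_run.items()}
    return out, mean, sd


# ---------------------------------------------------------------------------
# Zero-phase low-pass filtering
# ---------------------------------------------------------------------------

def _linear_pad(x: np.ndarray, pad_points: int, fit_points: int) -> np.ndarray:
    """Extend both ends with points on the least-squares line through the
    nearest ``fit_points`` original samples of that end."""
    if x.size <= fit_points:
        raise ParameterError(
            f"series of {x.size} samples too short for a {fit_points}-point "
            "pad fit")
    idx = np.arange(fit_points, dtype=float)
    slope0, inter0 = np.polyfit(idx, x[:fit_points], 1)
    left = inter0 + slope0 * np.arange(-pad_points, 0, dtype=float)
    slope1, inter1 = np.polyfit(idx, x[-fit_points:], 1)
    right = inter1 + slope1 * np.arange(fit_points, fit_points + pad_points,
                                        dtype=float)
    return np.concatenate([left, x, right])


def lowpass_zero_phase(x: np.ndarray,
                       rate: float = 500.0,
                       cutoff_hz: float = 4.0,
                       order: int = 3,
                       pad_points: int = 200,
                       pad_fit_points: int = 50) -> np.ndarray:
    """Forward-backward low-pass Butterworth with linear edge padding.

    The padded series is filtered, reversed, filtered again, restored to
    its original orientation and trimmed.  Net phase shift is zero and
    the magnitude response is the square of a single pass, so a sinusoid
    at the cutoff comes out at half its input amplitude.  Each pass is
    initialized at the filter's step steady state for the first padded
    sample, so a constant series passes through exactly (DC gain 1).
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= rate / 2:
        raise ParameterError("cutoff must be below the Nyquist rate")
    if cutoff_hz <= 0 or order <= 0:
        raise ParameterError("cutoff and order must be positive")
    b, a = scipy.signal.butter(order, cutoff_hz, btype="low", fs=rate)
    zi = scipy.signal.lfilter_zi(b, a)
    padded = _linear_pad(x, pad_points, pad_fit_points)
    forward, _ = scipy.signal.lfilter(b, a, padded, zi=zi * padded[0])
    rev = forward[::-1]
    backward, _ = scipy.signal.lfilter(b, a, rev, zi=zi * rev[0])
    out = backward[::-1]
    return out[pad_points:out.size - pad_points]


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    runs: dict[str, SampleSeries]  # pupil in filtered z-units
    blinks: list[BlinkInterval]
    mean: float
    sd: float


def preprocess_session(series_by_run: Mapping[str, SampleSeries],
                       config: AnalysisConfig | None = None) -> PreprocessResult:
    """Run the full preprocessing chain on one session.

    Stage order (default): detect blinks -> interpolate -> z-score the
    concatenation -> low-pass each run.  With
    ``config.zscore_before_interpolation`` the global mean/SD are taken
    from the raw concatenation instead.  ``config.filter_scope`` selects
    filtering per run (default; runs are temporally discontinuous) or on
    the concatenated session.
    """
    config = AnalysisConfig() if config is None else config
    config.validate()
    blinks: list[BlinkInterval] = []
    interpolated: dict[str, SampleSeries] = {}
    for run_id, series in series_by_run.items():
        ivs = detect_blinks(series, config.blink_pad)
        blinks.extend(ivs)
        interpolated[run_id] = interpolate_blinks(series, ivs)

    if config.zscore_before_interpolation:
        _, mean, sd = zscore_series(series_by_run)
        zruns = {rid: s.replace(pupil=(s.pupil - mean) / sd)
                 for rid, s in interpolated.items()}
    else:
        zruns, mean, sd = zscore_series(interpolated)

    def _filt(x: np.ndarray) -> np.ndarray:
        return lowpass_zero_phase(x, rate=config.rate,
                                  cutoff_hz=config.lowpass_hz,
                                  order=config.filter_order,
                                  pad_points=config.pad_points,
                                  pad_fit_points=config.pad_fit_points)

    if config.filter_scope == "run":
        filtered = {rid: s.replace(pupil=_filt(s.pupil))
                    for rid, s in zruns.items()}
    else:
        run_ids = list(zruns)
        lengths = [zruns[r].n_samples for r in run_ids]
        joint = _filt(np.concatenate([zruns[r].pupil for r in run_ids]))
        splits = np.split(joint, np.cumsum(lengths)[:-1])
        filtered = {rid: zruns[rid].replace(pupil=seg)
                    for rid, seg in zip(run_ids, splits)}
    return PreprocessResult(runs=filtered, blinks=blinks, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Gaze summaries
# ---------------------------------------------------------------------------

def gaze_time_course(series_by_run: Mapping[str, SampleSeries],
                     events: pd.DataFrame,
                     trial_samples: int = 7500) -> pd.DataFrame | None:
    """Per-sample mean gaze position across trials, split by trial type.

    Returns a tidy frame with columns ``trial_type``, ``sample``,
    ``gaze_x``, ``gaze_y``, or ``None`` (with a warning) when gaze
    columns are absent.
    """
    if not all(s.has_gaze for s in series_by_run.values()):
        logger.warning("gaze columns absent; skipping gaze time course")
        return None
    frames = []
    for trial_type, grp in events.groupby("trial_type"):
        gx = epoch_trials(series_by_run, grp, trial_samples, source="gaze_x")
        gy = epoch_trials(series_by_run, grp, trial_samples, source="gaze_y")
        frames.append(pd.DataFrame({
            "trial_type": trial_type,
            "sample": np.arange(trial_samples),
            "gaze_x": gx.data.mean(axis=0),
            "gaze_y": gy.data.mean(axis=0),
        }))
    return pd.concat(frames, ignore_index=True)
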