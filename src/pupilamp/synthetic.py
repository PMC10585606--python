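"""Synthetic eye-tracking sessions with known ground truth.

The generator emulates a fixation experiment in which pupil size is
recorded at 500 samples/s while a participant performs a demanding RSVP
task for 15 s per trial.  Each run holds 17 trials at one reward level
(high or low); on 75% of trials an unattended peripheral grating with a
contrast and spatial-frequency level is shown, on the rest nothing is.

Each trial's pupil trace is the sum of

* a *task-related* dilation kernel whose amplitude scales with the run's
  reward level (the arousal proxy),
* on stim trials only, a *stimulus-evoked* constriction kernel confined
  to the first ~4 s, scaled by a gain that by default is multiplicative
  in contrast and spatial frequency (so their factorial interaction is
  part of the ground truth), and
* stationary AR(1) noise, blink dropouts and a tracker baseline.

Kernel shapes are beta-density bumps with compact support: they start
and end at exactly zero inside the trial, which makes noise-free cohorts
exactly reconstructible by the downstream template regression.  The true
per-trial amplitudes are recorded row-aligned with the emitted trial
table, so every downstream stage can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .core_io import SampleSeries, write_events, write_samples
from .errors import FormatError, ParameterError


@dataclass
class GenerativeParams:
    """Parameters of the synthetic cohort generator.

    Amplitudes are in "signal units"; the emitted pupil column is
    ``baseline_pupil + pupil_unit_scale * signal`` in arbitrary tracker
    units, which the preprocessing z-scoring later removes.
    """

    n_subjects: int = 30
    runs_per_subject: int = 6
    trials_per_run: int = 17
    p_stim: float = 0.75
    rate: float = 500.0
    trial_samples: int = 7500
    # Recorded trial length; only the first trial_samples are analyzed.
    # Slightly longer than the 15-s analysis window, mimicking recordings
    # in which the analyzed window is the minimal trial length.
    trial_spacing_s: float = 16.0
    # Baseline lead-in/lead-out recorded before the first and after the
    # last trial of each run (the tracker runs before the first precue).
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    contrast_levels: tuple[float, ...] = (0.2, 1.0)
    sf_levels_cpd: tuple[float, ...] = (0.5, 0.8, 1.3, 2.0, 3.2)
    # Task-related (dilatory) amplitude per reward level.
    task_amp_high: float = 1.5
    task_amp_low: float = 1.0
    # Stimulus-evoked (constriction) gain surface g(c, s).
    stim_base_gain: float = 0.8
    contrast_exponent: float = 0.7
    sf_exponent: float = 0.4
    stim_gain_mode: str = "multiplicative"  # or "additive"
    # Which component the reward manipulation drives.  "task" is the
    # default double-dissociation ground truth; "stim" routes the same
    # high/low gain ratio onto the stimulus-evoked gain instead.
    reward_target: str = "task"
    # Kernel timing (seconds).
    task_peak_s: float = 2.5
    task_support_s: float = 10.0
    stim_peak_s: float = 1.2
    stim_support_s: float = 4.0
    subject_shape_jitter: float = 0.1
    # Per-trial lognormal amplitude jitter (sigma of log, mean-preserving).
    amp_jitter: float = 0.2
    # Additive AR(1) noise (stationary SD in signal units).
    noise_sd: float = 0.3
    ar1_coef: float = 0.99
    blink_rate_per_min: float = 15.0
    blink_dur_ms: tuple[float, float] = (100.0, 400.0)
    baseline_pupil: float = 1200.0
    pupil_unit_scale: float = 100.0
    gaze_jitter_deg: float = 0.15
    accuracy: float = 0.76
    miss_rate: float = 0.04
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_stim <= 1.0:
            raise ParameterError("p_stim must be in [0, 1]")
        if self.noise_sd < 0 or self.amp_jitter < 0:
            raise ParameterError("noise levels must be >= 0")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ParameterError("ar1_coef must be in [0, 1)")
        if any(not 0 < c <= 1 for c in self.contrast_levels):
            raise ParameterError("contrast levels must be in (0, 1]")
        if any(s <= 0 for s in self.sf_levels_cpd):
            raise ParameterError("spatial frequencies must be positive")
        if min(self.task_amp_high, self.task_amp_low,
               self.stim_base_gain) < 0:
            raise ParameterError("amplitude gains must be >= 0")
        trial_s = self.trial_samples / self.rate
        if self.task_support_s >= trial_s or self.stim_support_s >= trial_s:
            raise ParameterError("kernel support must end before the trial does")
        if self.trial_spacing_s < trial_s:
            raise ParameterError("trial_spacing_s must cover the analyzed "
                                 "window")
        for name in ("n_subjects", "runs_per_subject", "trials_per_run",
                     "trial_samples"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.stim_gain_mode not in ("multiplicative", "additive"):
            raise ParameterError("stim_gain_mode must be 'multiplicative' "
                                 "or 'additive'")
        if self.reward_target not in ("task", "stim"):
            raise ParameterError("reward_target must be 'task' or 'stim'")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_config(self, **overrides) -> "AnalysisConfig":
        """AnalysisConfig whose rate and trial window match this generator."""
        from .core_io import AnalysisConfig
        kwargs = {"rate": self.rate, "trial_samples": self.trial_samples,
                  "rng_seed": self.rng_seed}
        kwargs.update(overrides)
        return AnalysisConfig(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown generator keys: {sorted(unknown)}")
        for key in ("contrast_levels", "sf_levels_cpd", "blink_dur_ms"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        params = cls(**payload)
        params.validate()
        return params


@dataclass
class SubjectSession:
    """One synthetic participant: raw runs, trial table and ground truth."""

    subject_id: str
    runs: dict[str, SampleSeries]
    events: pd.DataFrame
    truth: pd.DataFrame  # row-aligned with ``events``
    kernels: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Response kernels
# ---------------------------------------------------------------------------

def _beta_bump(trial_samples: int, rate: float, peak_s: float,
               support_s: float, rise_exponent: float = 3.0) -> np.ndarray:
    """Unit-peak bump ``(t/T)^a (1-t/T)^b`` on [0, T], zero elsewhere.

    The exponent ``b`` is chosen so the continuous maximum sits exactly
    at ``peak_s``.  Compact support and a smooth (C2) onset keep the
    waveform and its low-pass-filtered version confined to the trial,
    matching the sluggish onset of real pupil responses.
    """
    if peak_s <= 0 or support_s <= peak_s:
        raise ParameterError("need 0 < peak_s < support_s")
    if trial_samples <= 0 or rate <= 0:
        raise ParameterError("trial_samples and rate must be positive")
    a = rise_exponent
    b = a * (support_s - peak_s) / peak_s
    t = np.arange(trial_samples) / rate
    x = np.clip(t / support_s, 0.0, 1.0)
    w = np.where(t < support_s, x ** a * (1.0 - x) ** b, 0.0)
    peak = w.max()
    if peak <= 0:
        raise ParameterError("kernel support shorter than one sample")
    return w / peak


def make_task_waveform(trial_samples: int = 7500, rate: float = 500.0,
                       peak_s: float = 2.5,
                       support_s: float = 10.0) -> np.ndarray:
    """Unit-peak dilatory (positive) task-related kernel.

    Rises after trial start, peaks mid-trial and returns to baseline
    before the trial ends, mimicking the arousal-linked dilation
    entrained to trial timing.
    """
    return _beta_bump(trial_samples, rate, peak_s, support_s)


def stim_gain(contrast: float, sf: float, params: GenerativeParams) -> float:
    """Constriction gain g(c, s) for one contrast x spatial-frequency cell.

    Multiplicative by default, ``g = g0 * c**pc * (s/s_max)**ps``, which
    makes the factorial contrast-by-frequency interaction part of the
    ground truth; the additive variant ``g = g0 * (c**pc + (s/s_max)**ps)/2``
    is interaction-free on the amplitude scale and serves calibration
    studies.
    """
    if contrast not in params.contrast_levels:
        raise ParameterError(f"unknown contrast level {contrast!r}")
    if sf not in params.sf_levels_cpd:
        raise ParameterError(f"unknown spatial frequency {sf!r}")
    gc = contrast ** params.contrast_exponent
    gs = (sf / max(params.sf_levels_cpd)) ** params.sf_exponent
    if params.stim_gain_mode == "multiplicative":
        return params.stim_base_gain * gc * gs
    return params.stim_base_gain * 0.5 * (gc + gs)


def make_stim_waveform(contrast: float, sf: float, params: GenerativeParams,
                       trial_samples: int | None = None,
                       rate: float | None = None,
                       peak_s: float | None = None,
                       support_s: float | None = None) -> np.ndarray:
    """Stimulus-evoked constriction kernel, scaled by ``stim_gain(c, s)``.

    Negative-lobed and confined to the stimulus/response epoch (first
    ~4 s of the trial); its minimum equals ``-stim_gain(c, s)``.
    """
    trial_samples = params.trial_samples if trial_samples is None else trial_samples
    rate = params.rate if rate is None else rate
    peak_s = params.stim_peak_s if peak_s is None else peak_s
    support_s = params.stim_support_s if support_s is None else support_s
    g = stim_gain(contrast, sf, params)
    return -g * _beta_bump(trial_samples, rate, peak_s, support_s)


# ---------------------------------------------------------------------------
# Noise and artifacts
# ---------------------------------------------------------------------------

def ar1_noise(n: int, sd: float, coef: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with the given stationary SD."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(scale=sd * np.sqrt(1.0 - coef ** 2), size=n)
    x0 = rng.normal(scale=sd)
    out, _ = scipy.signal.lfilter([1.0], [1.0, -coef], eps,
                                  zi=np.atleast_1d(coef * x0))
    return out


def _insert_blinks(pupil: np.ndarray, blink: np.ndarray, rate: float,
                   rate_per_min: float, dur_ms: tuple[float, float],
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Zero out Poisson-placed blink intervals; returns [start, end) pairs."""
    n = pupil.size
    minutes = n / rate / 60.0
    count = rng.poisson(rate_per_min * minutes)
    intervals = []
    for _ in range(count):
        dur = int(round(rng.uniform(*dur_ms) / 1000.0 * rate))
        start = int(rng.integers(0, max(1, n - dur)))
        end = min(n, start + max(1, dur))
        pupil[start:end] = 0.0
        blink[start:end] = True
        intervals.append((start, end))
    return intervals


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_kernels(params: GenerativeParams,
                     rng: np.random.Generator) -> dict:
    """Per-subject kernel shapes with lognormal peak-time jitter."""
    jit = params.subject_shape_jitter
    task_peak = params.task_peak_s * np.exp(rng.normal(0.0, jit)) if jit else params.task_peak_s
    stim_peak = params.stim_peak_s * np.exp(rng.normal(0.0, jit)) if jit else params.stim_peak_s
    task_peak = min(task_peak, 0.8 * params.task_support_s)
    stim_peak = min(stim_peak, 0.8 * params.stim_support_s)
    task = make_task_waveform(params.trial_samples, params.rate,
                              task_peak, params.task_support_s)
    stim_unit = _beta_bump(params.trial_samples, params.rate,
                           stim_peak, params.stim_support_s)
    return {"task": task, "stim_unit": stim_unit,
            "task_peak_s": task_peak, "stim_peak_s": stim_peak}


def _lognormal_factor(sigma: float, rng: np.random.Generator,
                      size=None) -> np.ndarray | float:
    """Mean-one multiplicative lognormal jitter."""
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma ** 2)


def generate_subject(params: GenerativeParams, subject_id: str,
                     seed: np.random.SeedSequence) -> SubjectSession:
    """Generate one participant's runs, events and ground truth."""
    params.validate()
    rng = np.random.default_rng(seed)
    kernels = _subject_kernels(params, rng)
    lead_in = int(round(params.lead_in_s * params.rate))
    lead_out = int(round(params.lead_out_s * params.rate))
    T = params.trial_samples
    spacing = int(round(params.trial_spacing_s * params.rate))
    n_run_samples = lead_in + (params.trials_per_run - 1) * spacing + T + lead_out
    ratio = (params.task_amp_high / params.task_amp_low
             if params.task_amp_low > 0 else 1.0)
    baseline = params.baseline_pupil + rng.normal(0.0, 0.03 * params.baseline_pupil)

    # Precompute the gain surface for all cells.
    cells = [(c, s) for c in params.contrast_levels for s in params.sf_levels_cpd]
    gain = {cell: stim_gain(*cell, params) for cell in cells}

    runs: dict[str, SampleSeries] = {}
    events_rows, truth_rows = [], []
    start_high = int(subject_id[-1]) % 2 == 0 if subject_id[-1].isdigit() else True
    for j in range(params.runs_per_subject):
        reward = "high" if (j % 2 == 0) == start_high else "low"
        run_id = f"{subject_id}_r{j}"
        signal = np.zeros(n_run_samples)
        if params.reward_target == "task":
            task_mean = (params.task_amp_high if reward == "high"
                         else params.task_amp_low)
            stim_reward_factor = 1.0
        else:  # reward routed onto the stimulus-evoked gain instead
            task_mean = params.task_amp_low
            stim_reward_factor = ratio if reward == "high" else 1.0

        for i in range(params.trials_per_run):
            onset = lead_in + i * spacing
            is_stim = rng.random() < params.p_stim
            task_amp = task_mean * _lognormal_factor(params.amp_jitter, rng)
            signal[onset:onset + T] += task_amp * kernels["task"]
            if is_stim:
                contrast, sf = cells[rng.integers(len(cells))]
                stim_amp = (gain[(contrast, sf)] * stim_reward_factor
                            * _lognormal_factor(params.amp_jitter, rng))
                signal[onset:onset + T] -= stim_amp * kernels["stim_unit"]
            else:
                contrast = sf = np.nan
                stim_amp = np.nan
            missed = rng.random() < params.miss_rate
            if missed:
                response, rt = "missed", np.nan
            else:
                response = ("correct" if rng.random() < params.accuracy
                            else "incorrect")
                rt = float(np.exp(rng.normal(np.log(0.55), 0.25)))
            events_rows.append({
                "run_id": run_id, "trial_index": i, "onset_sample": onset,
                "trial_type": "stim" if is_stim else "null", "reward": reward,
                "contrast": contrast, "spatial_frequency": sf,
                "response": response, "reaction_time": rt,
            })
            truth_rows.append({
                "run_id": run_id, "trial_index": i,
                "true_task_amp": task_amp, "true_stim_amp": stim_amp,
            })

        signal += ar1_noise(n_run_samples, params.noise_sd, params.ar1_coef, rng)
        pupil = baseline + params.pupil_unit_scale * signal
        blink = np.zeros(n_run_samples, dtype=bool)
        if params.blink_rate_per_min > 0:
            _insert_blinks(pupil, blink, params.rate,
                           params.blink_rate_per_min, params.blink_dur_ms, rng)
        if params.gaze_jitter_deg > 0:
            gaze_x = rng.normal(0.0, params.gaze_jitter_deg, n_run_samples)
            gaze_y = rng.normal(0.0, params.gaze_jitter_deg, n_run_samples)
        else:
            gaze_x = np.zeros(n_run_samples)
            gaze_y = np.zeros(n_run_samples)
        runs[run_id] = SampleSeries(
            run_id=run_id, pupil=pupil,
            timestamp_ms=np.arange(n_run_samples) * 1000.0 / params.rate,
            gaze_x=gaze_x, gaze_y=gaze_y, blink=blink, rate=params.rate)

    return SubjectSession(
        subject_id=subject_id, runs=runs,
        events=pd.DataFrame(events_rows), truth=pd.DataFrame(truth_rows),
        kernels=kernels)


def iter_cohort(params: GenerativeParams) -> Iterator[SubjectSession]:
    """Yield subjects one at a time (memory-friendly for large cohorts)."""
    params.validate()
    root = np.random.SeedSequence(params.rng_seed)
    children = root.spawn(params.n_subjects)
    for k, child in enumerate(children):
        yield generate_subject(params, f"s{k:02d}", child)


def generate_cohort(params: GenerativeParams) -> list[SubjectSession]:
    """Generate the full cohort as a list (deterministic in ``rng_seed``)."""
    return list(iter_cohort(params))


def write_subject(session: SubjectSession, out_dir: str | Path) -> None:
    """Write one subject's samples.tsv / events.tsv / truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples(session.runs, out / "samples.tsv")
    write_events(session.events, out / "events.tsv")
    session.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Direct trial-matrix simulation (for resampling studies)
# ---------------------------------------------------------------------------

def null_trial_matrix(n_per_reward: int,
                      trial_samples: int = 7500,
                      rate: float = 500.0,
                      amp_high: float = 1.0,
                      amp_low: float = 1.0,
                      amp_jitter: float = 0.2,
                      noise_sd: float = 0.3,
                      ar1_coef: float = 0.99,
                      peak_s: float = 2.5,
                      support_s: float = 10.0,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate already-epoched null trials for one participant.

    Returns ``(Y, labels)`` with ``Y`` of shape
    ``(2 * n_per_reward, trial_samples)`` and reward labels
    ``{"high", "low"}``.  Used by pseudo-trial-split calibration studies,
    which operate on epoched null trials and need no blink or filtering
    machinery.
    """
    rng = np.random.default_rng() if rng is None else rng
    kernel = make_task_waveform(trial_samples, rate, peak_s, support_s)
    labels = np.array(["high"] * n_per_reward + ["low"] * n_per_reward)
    means = np.where(labels == "high", amp_high, amp_low)
    amps = means * _lognormal_factor(amp_jitter, rng, size=labels.size)
    noise = np.vstack([ar1_noise(trial_samples, noise_sd, ar1_coef, rng)
                       for _ in range(labels.size)]) if noise_sd > 0 else 0.0
    Y = amps[:, None] * kernel[None, :] + noise
    return Y, labels
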