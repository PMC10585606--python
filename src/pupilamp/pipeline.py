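"""End-to-end orchestration: preprocess -> epoch -> templates -> amplitudes.

Glue between the stage modules; each step is importable on its own, this
module just chains them for a whole cohort and prepares the inputs of
the resampling and inference layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .amplitude import ResponseTemplate, build_templates, fit_session, participant_means
from .core_io import AnalysisConfig, SampleSeries, TrialMatrix, epoch_trials
from .errors import ParameterError
from .preprocess import BlinkInterval, PreprocessResult, preprocess_session
from .resampling import BootstrapResult, bootstrap_reward_null


@dataclass
class SubjectResult:
    subject_id: str
    amplitudes: pd.DataFrame
    templates: dict[tuple[str, str], ResponseTemplate]
    null_data: tuple[np.ndarray, np.ndarray]  # (Y_null, reward labels)
    blinks: list[BlinkInterval]
    mean_r2: dict[str, float]


def analyze_subject(series_by_run: Mapping[str, SampleSeries],
                    events: pd.DataFrame,
                    config: AnalysisConfig | None = None,
                    subject_id: str = "s00") -> SubjectResult:
    """Run the full single-participant chain and keep the bootstrap inputs."""
    config = AnalysisConfig() if config is None else config
    pre = preprocess_session(series_by_run, config)
    tm = epoch_trials(pre.runs, events, config.trial_samples)
    templates = build_templates(tm)
    amps = fit_session(tm, templates)
    amps.insert(0, "subject", subject_id)
    null_rows = np.flatnonzero((tm.meta["trial_type"] == "null").to_numpy())
    null_data = (tm.data[null_rows],
                 tm.meta["reward"].to_numpy()[null_rows])
    mean_r2 = {tt: float(amps.loc[amps["trial_type"] == tt, "r_squared"].mean())
               for tt in ("null", "stim")}
    return SubjectResult(subject_id=subject_id, amplitudes=amps,
                         templates=templates, null_data=null_data,
                         blinks=pre.blinks, mean_r2=mean_r2)


@dataclass
class CohortResult:
    amplitudes: pd.DataFrame                     # all subjects, trial level
    null_data: list[tuple[np.ndarray, np.ndarray]]
    subjects: list[str] = field(default_factory=list)

    def condition_means(self, by: tuple[str, ...] = ()) -> pd.DataFrame:
        return participant_means(self.amplitudes, by=by)

    def reward_difference(self, trial_type: str,
                          value: str = "beta") -> float:
        """Group mean of per-participant high-minus-low condition means."""
        pm = participant_means(self.amplitudes)
        sub = pm[pm["trial_type"] == trial_type]
        wide = sub.pivot_table(index="subject", columns="reward",
                               values=value).dropna()
        if wide.empty:
            raise ParameterError(f"no paired reward data for {trial_type!r}")
        return float((wide["high"] - wide["low"]).mean())


def analyze_cohort(sessions: Iterable[tuple[str, Mapping[str, SampleSeries],
                                            pd.DataFrame]],
                   config: AnalysisConfig | None = None) -> CohortResult:
    """Analyze an iterable of ``(subject_id, runs, events)`` sessions.

    Accepts a lazy iterable so large synthetic cohorts can be generated
    and analyzed one subject at a time.
    """
    config = AnalysisConfig() if config is None else config
    frames, null_data, subjects = [], [], []
    for subject_id, runs, events in sessions:
        res = analyze_subject(runs, events, config, subject_id=subject_id)
        frames.append(res.amplitudes)
        null_data.append(res.null_data)
        subjects.append(subject_id)
    if not frames:
        raise ParameterError("no sessions supplied")
    return CohortResult(amplitudes=pd.concat(frames, ignore_index=True),
                        null_data=null_data, subjects=subjects)


def cohort_sessions(cohort) -> Iterable[tuple[str, Mapping[str, SampleSeries],
                                              pd.DataFrame]]:
    """Adapt synthetic ``SubjectSession`` objects (or an iterator of them)."""
    for session in cohort:
        yield session.subject_id, session.runs, session.events


def run_bootstrap(result: CohortResult,
                  n_iter: int = 10000,
                  seed: int = 0,
                  smoothed: bool = False) -> BootstrapResult:
    """Split bootstrap against the cohort's actual reward differences.

    The pseudo-null distribution is compared with the actual null-trial
    reward difference, the pseudo-stim distribution with the actual
    stim-trial difference.
    """
    actual = {"pseudo_null": result.reward_difference("null"),
              "pseudo_stim": result.reward_difference("stim")}
    return bootstrap_reward_null(result.null_data, n_iter=n_iter, seed=seed,
                                 actual_diff=actual, smoothed=smoothed)


def bootstrap_summary(boot: BootstrapResult) -> dict:
    return {
        "n_iter": boot.n_iter,
        "seed": boot.seed,
        "aggregation": boot.aggregation,
        "actual_diff": boot.actual_diff,
        "p_value": boot.p_value,
        "null_dist_mean": {k: float(v.mean())
                           for k, v in boot.null_dist.items()},
        "null_dist_sd": {k: float(v.std()) for k, v in boot.null_dist.items()},
    }
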