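"""Response-template regression: per-trial pupil response amplitudes.

Phasic pupil responses are modeled as a linear system: each trial's
preprocessed time series Y (7500 samples) is a scaled copy of a
condition-specific *response template* plus an offset,

    Y = X @ beta,   X = [template, 1],

so ordinary least squares on the two-column design yields one response
amplitude (the template's coefficient) and an intercept per trial.

Templates are participant-specific condition means: the *null* template
for a reward level is the average of that level's null trials (the
task-related response); the *stim* template is the average of the same
level's stim trials after subtracting the un-normalized null template,
which isolates the stimulus-evoked constriction.  Four templates per
participant (stim/null x high/low reward).  Each template is z-scored
before entering the design so amplitudes share a common scale across
conditions; the stim-trial subtraction itself uses the raw (un-z-scored)
template because it must happen in signal units.

A positive stim-trial amplitude means a larger constriction-shaped
response (the template is constriction-shaped and kept as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import REWARD_LEVELS, TRIAL_TYPES, TrialMatrix
from .errors import RankError, ShapeError, TemplateError

#: grouping keys that define one template cell
TEMPLATE_KEYS = ("trial_type", "reward")


@dataclass
class ResponseTemplate:
    """Condition-specific mean waveform used as the shaped regressor."""

    trial_type: str
    reward: str
    waveform: np.ndarray       # z-scored, the actual regressor
    raw_waveform: np.ndarray   # pre-z-scoring mean, used for subtraction
    n_trials_averaged: int


def zscore_waveform(w: np.ndarray) -> np.ndarray:
    """Z-score with population SD; degenerate waveforms raise loudly."""
    sd = w.std()
    if not np.isfinite(sd) or sd < 1e-12 * max(1.0, np.abs(w).max()):
        raise TemplateError("template waveform has (near-)zero variance; "
                            "cannot z-score")
    return (w - w.mean()) / sd


def build_templates(trial_matrix: TrialMatrix
                    ) -> dict[tuple[str, str], ResponseTemplate]:
    """Build the four condition templates from one participant's trials.

    Raises :class:`TemplateError` naming the cell when a trial-type x
    reward cell is empty or its mean waveform is constant.
    """
    meta = trial_matrix.meta
    data = trial_matrix.data
    null_raw: dict[str, np.ndarray] = {}
    templates: dict[tuple[str, str], ResponseTemplate] = {}
    for reward in REWARD_LEVELS:
        rows = np.flatnonzero((meta["trial_type"] == "null").to_numpy()
                              & (meta["reward"] == reward).to_numpy())
        if rows.size == 0:
            raise TemplateError(f"no null trials for reward={reward!r}")
        raw = data[rows].mean(axis=0)
        null_raw[reward] = raw
        try:
            z = zscore_waveform(raw)
        except TemplateError as exc:
            raise TemplateError(f"null/{reward} template: {exc}") from exc
        templates[("null", reward)] = ResponseTemplate(
            "null", reward, z, raw, rows.size)
    for reward in REWARD_LEVELS:
        rows = np.flatnonzero((meta["trial_type"] == "stim").to_numpy()
                              & (meta["reward"] == reward).to_numpy())
        if rows.size == 0:
            raise TemplateError(f"no stim trials for reward={reward!r}")
        raw = (data[rows] - null_raw[reward]).mean(axis=0)
        try:
            z = zscore_waveform(raw)
        except TemplateError as exc:
            raise TemplateError(f"stim/{reward} template: {exc}") from exc
        templates[("stim", reward)] = ResponseTemplate(
            "stim", reward, z, raw, rows.size)
    return templates


def _ols_rows(Y: np.ndarray, template: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise OLS of Y on [template, 1]; returns (beta, intercept, r2)."""
    if Y.shape[-1] != template.size:
        raise ShapeError(f"trial length {Y.shape[-1]} != template length "
                         f"{template.size}")
    tc = template - template.mean()
    denom = tc @ tc
    if denom < 1e-12 * template.size * max(1.0, np.abs(template).max() ** 2):
        raise RankError("constant template: design matrix is rank deficient")
    ymean = Y.mean(axis=-1)
    Yc = Y - ymean[..., None]
    beta = Yc @ tc / denom
    intercept = ymean - beta * template.mean()
    ss_tot = np.einsum("...i,...i->...", Yc, Yc)
    resid = Yc - beta[..., None] * tc
    ss_res = np.einsum("...i,...i->...", resid, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return beta, intercept, r2


def estimate_trial_amplitude(trial_series: np.ndarray,
                             template: ResponseTemplate,
                             null_template: ResponseTemplate | None = None
                             ) -> dict:
    """Fit one trial; for stim trials pass the same-reward null template.

    The stim-trial response is isolated by subtracting the raw
    (un-z-scored) null template from the series before regression.
    Returns ``beta``, ``intercept``, ``r_squared`` and ``sd_measure``
    (the SD across time of the measured trial, the regression-free
    amplitude proxy).
    """
    y = np.asarray(trial_series, dtype=float)
    sd_measure = float(y.std())
    if template.trial_type == "stim":
        if null_template is None:
            raise TemplateError("stim-trial fit needs the same-reward null "
                                "template for subtraction")
        y = y - null_template.raw_waveform
    beta, intercept, r2 = _ols_rows(y[None, :], template.waveform)
    return {"beta": float(beta[0]), "intercept": float(intercept[0]),
            "r_squared": float(r2[0]), "sd_measure": sd_measure}


def fit_session(trial_matrix: TrialMatrix,
                templates: dict[tuple[str, str], ResponseTemplate]
                ) -> pd.DataFrame:
    """Estimate one amplitude per trial with its condition's template.

    Returns the trial metadata with ``beta``, ``intercept``,
    ``r_squared`` and ``sd_measure`` columns appended, row-aligned with
    the input matrix.
    """
    meta = trial_matrix.meta
    out = meta.copy()
    for col in ("beta", "intercept", "r_squared", "sd_measure"):
        out[col] = np.nan
    out["sd_measure"] = trial_matrix.data.std(axis=1)
    for (trial_type, reward), template in templates.items():
        rows = np.flatnonzero((meta["trial_type"] == trial_type).to_numpy()
                              & (meta["reward"] == reward).to_numpy())
        if rows.size == 0:
            continue
        Y = trial_matrix.data[rows]
        if trial_type == "stim":
            Y = Y - templates[("null", reward)].raw_waveform
        beta, intercept, r2 = _ols_rows(Y, template.waveform)
        out.loc[out.index[rows], "beta"] = beta
        out.loc[out.index[rows], "intercept"] = intercept
        out.loc[out.index[rows], "r_squared"] = r2
    return out


def trial_sd(trial_series: np.ndarray) -> float:
    """SD of one trial's time series (population SD across samples)."""
    y = np.asarray(trial_series, dtype=float)
    if y.size < 2:
        raise ShapeError("trial SD needs at least 2 samples")
    return float(y.std())


def participant_means(amplitudes: pd.DataFrame,
                      by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-participant condition means, the unit of all group inference.

    Groups by subject, trial type and reward plus any extra keys
    (e.g. ``("contrast", "spatial_frequency")`` for stim trials) and
    averages ``beta`` and ``sd_measure``.  Cells without trials are
    simply absent from the output.
    """
    if amplitudes.empty:
        raise TemplateError("empty amplitude table")
    keys = ["subject", "trial_type", "reward", *by]
    grouped = (amplitudes
               .groupby(keys, dropna=False)
               .agg(beta=("beta", "mean"),
                    sd_measure=("sd_measure", "mean"),
                    r_squared=("r_squared", "mean"),
                    n_trials=("beta", "size"))
               .reset_index())
    return grouped
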