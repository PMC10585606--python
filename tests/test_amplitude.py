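"""Template construction and per-trial OLS amplitude estimation."""

import numpy as np
import pandas as pd
import pytest

import pupilamp as pa
from pupilamp.amplitude import ResponseTemplate, _ols_rows, zscore_waveform
from pupilamp.errors import RankError, ShapeError, TemplateError

from conftest import cohort_truth


def _trial_matrix(data, trial_types, rewards):
    meta = pd.DataFrame({"trial_type": trial_types, "reward": rewards})
    return pa.TrialMatrix(data=np.asarray(data, float), meta=meta)


def _template(waveform, trial_type="null", reward="high"):
    w = np.asarray(waveform, float)
    return ResponseTemplate(trial_type, reward, zscore_waveform(w), w, 1)


class TestTemplates:
    def test_four_templates_z_scored(self, clean_result, clean_cohort,
                                     clean_params):
        session = clean_cohort[0]
        cfg = clean_params.analysis_config()
        pre = pa.preprocess_session(session.runs, cfg)
        tm = pa.epoch_trials(pre.runs, session.events, cfg.trial_samples)
        templates = pa.build_templates(tm)
        assert set(templates) == {("null", "high"), ("null", "low"),
                                  ("stim", "high"), ("stim", "low")}
        for tpl in templates.values():
            assert abs(tpl.waveform.mean()) < 1e-10
            assert abs(tpl.waveform.std() - 1.0) < 1e-10
            assert tpl.n_trials_averaged > 0

    def test_empty_cell_raises_naming_cell(self):
        tm = _trial_matrix(np.random.default_rng(0).normal(size=(4, 50)),
                           ["null"] * 4, ["high"] * 4)
        with pytest.raises(TemplateError, match="reward='low'"):
            pa.build_templates(tm)

    def test_stim_equal_to_null_template_degenerate(self):
        """Stim trials identical to the null mean leave a zero stim template."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=60)
        data = np.tile(base, (8, 1))
        tm = _trial_matrix(data, ["null", "stim"] * 4,
                           ["high", "high", "low", "low"] * 2)
        with pytest.raises(TemplateError, match="stim"):
            pa.build_templates(tm)

    def test_noise_free_stim_template_matches_true_kernel(self, clean_cohort,
                                                          clean_params):
        session = clean_cohort[0]
        cfg = clean_params.analysis_config()
        pre = pa.preprocess_session(session.runs, cfg)
        tm = pa.epoch_trials(pre.runs, session.events, cfg.trial_samples)
        templates = pa.build_templates(tm)
        truth = -session.kernels["stim_unit"]  # constriction is negative
        for reward in ("high", "low"):
            raw = templates[("stim", reward)].raw_waveform
            cos = (raw @ truth) / np.sqrt((raw @ raw) * (truth @ truth))
            assert cos > 0.999


class TestTrialFit:
    def test_self_regression(self):
        tpl = _template(np.sin(np.linspace(0, 6, 200)))
        res = pa.estimate_trial_amplitude(tpl.waveform, tpl)
        assert res["beta"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_affine_trial_closed_form(self):
        tpl = _template(np.sin(np.linspace(0, 6, 200)))
        y = 2.5 * tpl.waveform + 0.3
        res = pa.estimate_trial_amplitude(y, tpl)
        assert res["beta"] == pytest.approx(2.5)
        assert res["intercept"] == pytest.approx(0.3)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_orthogonal_trial_zero_amplitude(self):
        tpl = _template(np.sin(np.linspace(0, 6, 200)))
        res = pa.estimate_trial_amplitude(np.full(200, 1.7), tpl)
        assert res["beta"] == pytest.approx(0.0, abs=1e-12)
        assert res["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_generic_lstsq_solver(self, rng):
        """Closed-form OLS agrees with a generic solver on random data."""
        for _ in range(20):
            t = rng.normal(size=120)
            tpl = _template(t)
            y = rng.normal(size=120)
            res = pa.estimate_trial_amplitude(y, tpl)
            X = np.column_stack([tpl.waveform, np.ones(120)])
            beta, intercept = np.linalg.lstsq(X, y, rcond=None)[0]
            assert res["beta"] == pytest.approx(beta, abs=1e-10)
            assert res["intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_scale_equivariance(self, rng):
        tpl = _template(rng.normal(size=150))
        y = rng.normal(size=150)
        a = pa.estimate_trial_amplitude(y, tpl)
        b = pa.estimate_trial_amplitude(3.0 * y, tpl)
        assert b["beta"] == pytest.approx(3.0 * a["beta"])
        assert b["intercept"] == pytest.approx(3.0 * a["intercept"])
        assert b["r_squared"] == pytest.approx(a["r_squared"])

    def test_z_scoring_makes_amplitudes_template_scale_free(self, rng):
        """Affinely related templates give identical amplitudes once z-scored."""
        base = rng.normal(size=100)
        y = rng.normal(size=100)
        a = pa.estimate_trial_amplitude(y, _template(base))
        b = pa.estimate_trial_amplitude(y, _template(5.0 * base - 2.0))
        assert a["beta"] == pytest.approx(b["beta"])

    def test_constant_template_and_length_mismatch(self):
        with pytest.raises(TemplateError):
            _template(np.full(100, 2.0))
        tpl = _template(np.sin(np.linspace(0, 6, 200)))
        with pytest.raises(ShapeError):
            pa.estimate_trial_amplitude(np.zeros(150), tpl)
        degenerate = ResponseTemplate("null", "high", np.zeros(100),
                                      np.zeros(100), 1)
        with pytest.raises(RankError):
            pa.estimate_trial_amplitude(np.zeros(100), degenerate)

    def test_stim_fit_requires_null_template(self):
        tpl = _template(np.sin(np.linspace(0, 6, 200)), trial_type="stim")
        with pytest.raises(TemplateError):
            pa.estimate_trial_amplitude(np.zeros(200), tpl,
                                        null_template=None)


class TestTrialSD:
    def test_closed_forms(self):
        assert pa.trial_sd(np.full(100, 4.2)) == 0.0
        square = np.tile([-1.0, 1.0], 50)
        assert pa.trial_sd(square) == pytest.approx(1.0)

    def test_matches_two_pass_variance(self, rng):
        y = rng.normal(size=777)
        mean = sum(y) / len(y)
        var = sum((v - mean) ** 2 for v in y) / len(y)
        assert pa.trial_sd(y) == pytest.approx(np.sqrt(var), abs=1e-12)


class TestSessionFit:
    def test_cardinality_and_labels(self, fast_result, fast_cohort):
        amps = fast_result.amplitudes
        assert len(amps) == 3 * 2 * 17
        assert set(amps["subject"]) == {s.subject_id for s in fast_cohort}
        assert amps["beta"].notna().all()
        assert amps["r_squared"].between(0, 1).all()

    def test_noise_free_recovery_scaled_by_template(self, clean_result,
                                                    clean_cohort):
        truth = cohort_truth(clean_cohort)
        merged = clean_result.amplitudes.merge(
            truth, on=["subject", "run_id", "trial_index"])
        null = merged[merged["trial_type"] == "null"]
        assert (null["r_squared"] > 1 - 1e-9).all()
        # the template z-scale factor is participant-specific
        for _, grp in null.groupby("subject"):
            ratio = (grp["beta"] / grp["true_task_amp"]).to_numpy()
            assert np.ptp(ratio) < 1e-9 * np.abs(ratio).mean()

    def test_wrong_reward_template_fits_worse(self, fast_cohort, fast_params):
        """Swapping reward templates lowers fit quality on reward-scaled data."""
        session = fast_cohort[0]
        cfg = fast_params.analysis_config()
        pre = pa.preprocess_session(session.runs, cfg)
        tm = pa.epoch_trials(pre.runs, session.events, cfg.trial_samples)
        templates = pa.build_templates(tm)
        right = pa.fit_session(tm, templates)
        swapped = {(tt, {"high": "low", "low": "high"}[r]): tpl
                   for (tt, r), tpl in templates.items()}
        swapped = {k: ResponseTemplate(k[0], k[1], t.waveform, t.raw_waveform,
                                       t.n_trials_averaged)
                   for k, t in swapped.items()}
        wrong = pa.fit_session(tm, swapped)
        assert wrong["r_squared"].mean() < right["r_squared"].mean()


class TestParticipantMeans:
    def test_simple_cell_mean(self):
        amps = pd.DataFrame({
            "subject": ["s0"] * 2, "trial_type": ["null"] * 2,
            "reward": ["high"] * 2, "beta": [1.0, 3.0],
            "sd_measure": [0.5, 1.5], "r_squared": [1.0, 1.0]})
        pm = pa.participant_means(amps)
        assert len(pm) == 1
        assert pm.loc[0, "beta"] == 2.0
        assert pm.loc[0, "sd_measure"] == 1.0
        assert pm.loc[0, "n_trials"] == 2

    def test_stim_cells_bounded_by_design(self, fast_result):
        pm = fast_result.condition_means(by=("contrast", "spatial_frequency"))
        stim = pm[pm["trial_type"] == "stim"]
        cells = stim.groupby(["subject", "reward"]).size()
        assert (cells <= 10).all()  # 2 contrasts x 5 spatial frequencies

    def test_grand_mean_equals_trial_mean_only_when_balanced(self):
        amps = pd.DataFrame({
            "subject": ["s0"] * 4 + ["s1"] * 2,
            "trial_type": ["null"] * 6, "reward": ["high"] * 6,
            "beta": [1.0, 1.0, 1.0, 1.0, 4.0, 4.0],
            "sd_measure": 1.0, "r_squared": 1.0})
        pm = pa.participant_means(amps)
        grand_of_means = pm["beta"].mean()          # (1 + 4) / 2
        trial_mean = amps["beta"].mean()            # 8/6, unbalanced
        assert grand_of_means == pytest.approx(2.5)
        assert trial_mean != pytest.approx(grand_of_means)
        balanced = amps.iloc[[0, 1, 4, 5]]
        pmb = pa.participant_means(balanced)
        assert pmb["beta"].mean() == pytest.approx(balanced["beta"].mean())
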