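"""Group-level statistics: paired tests, rank and mixed factorial ANOVAs.

The inference layer reproduces the dissociation logic: reward effects on
per-participant mean amplitudes are tested with paired t and Wilcoxon
signed-rank tests (normality screened by Shapiro-Wilk, Wilcoxon CIs via
the BCa bootstrap); stimulus-feature effects on trial-level stim
amplitudes are tested with mixed ANOVAs (subject entering as a random
blocking factor) and, because amplitude distributions are typically
non-normal, with the nonparametric Scheirer-Ray-Hare (SRH) rank test.

SRH construction: rank all N observations jointly (mid-ranks for ties),
compute the factorial ANOVA sums of squares on the ranks, and refer

    H_effect = SS_effect / MS_total,   MS_total = SS_total / (N - 1)

to a chi-square with the effect's df.  Using the observed rank variance
for MS_total builds the tie correction in: with a single factor this H
is exactly the tie-corrected Kruskal-Wallis statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DesignError, ParameterError
from .resampling import BootstrapResult, bca_ci

_TERM_RE = re.compile(r"C\(Q\('([^']+)'\)\)")


@dataclass
class TestResult:
    """One row of a statistics table."""

    method: str
    statistic: float
    df: float | None
    p: float
    estimate: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    n: int | None = None
    note: str = ""

    def to_row(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "df": self.df, "p": self.p, "estimate": self.estimate,
                "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "n": self.n,
                "note": self.note}


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------

def paired_comparison(x: np.ndarray, y: np.ndarray,
                      alpha: float = 0.05,
                      n_boot: int = 10000,
                      seed: int = 0) -> dict[str, TestResult]:
    """Shapiro-Wilk on the differences, paired t, and Wilcoxon signed-rank.

    ``x`` and ``y`` are participant-paired observations (e.g. high- and
    low-reward condition means).  The t test reports its parametric CI
    of the mean difference; the Wilcoxon row carries a BCa bootstrap CI
    of the mean difference.  All-zero differences leave the Wilcoxon
    degenerate (statistic and p undefined, noted as such).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("paired samples must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    d = x - y
    est = float(d.mean())
    n = int(d.size)
    results: dict[str, TestResult] = {}
    if np.all(d == d[0]):
        results["shapiro"] = TestResult("shapiro_wilk", np.nan, float(n - 1),
                                        np.nan, n=n,
                                        note="degenerate: constant differences")
    else:
        sw = scipy.stats.shapiro(d)
        results["shapiro"] = TestResult("shapiro_wilk", float(sw.statistic),
                                        float(n - 1), float(sw.pvalue), n=n)
    if np.all(d == d[0]):  # zero-variance differences: t is 0/0
        results["t_test"] = TestResult(
            "paired_t", 0.0 if d[0] == 0 else np.inf, float(n - 1),
            1.0 if d[0] == 0 else 0.0, estimate=est, ci_lo=est, ci_hi=est,
            n=n, note="degenerate: constant differences")
    else:
        tt = scipy.stats.ttest_rel(x, y)
        ci = tt.confidence_interval(1.0 - alpha)
        results["t_test"] = TestResult(
            "paired_t", float(tt.statistic), float(tt.df), float(tt.pvalue),
            estimate=est, ci_lo=float(ci.low), ci_hi=float(ci.high), n=n)
    if np.all(d == 0.0):
        results["wilcoxon"] = TestResult(
            "wilcoxon_signed_rank", np.nan, None, np.nan, estimate=0.0,
            n=n, note="degenerate: all differences zero")
    else:
        wr = scipy.stats.wilcoxon(x, y, method="approx")
        lo, hi = bca_ci(d, np.mean, n_boot=n_boot, alpha=alpha, seed=seed)
        # scipy's z is computed from the smaller rank sum and so is always
        # <= 0; report it signed by the direction of the effect
        z = float(np.copysign(abs(wr.zstatistic), est)) if est != 0 \
            else float(wr.zstatistic)
        results["wilcoxon"] = TestResult(
            "wilcoxon_signed_rank", z, None,
            float(wr.pvalue), estimate=est, ci_lo=lo, ci_hi=hi, n=n)
    return results


# ---------------------------------------------------------------------------
# Factorial tests
# ---------------------------------------------------------------------------

def _clean_term(term: str) -> str:
    return _TERM_RE.sub(r"\1", term)


def _anova_sums(values: np.ndarray, factors: dict[str, np.ndarray],
                subject: np.ndarray | None = None, typ: int = 2
                ) -> pd.DataFrame:
    """Factorial OLS ANOVA table (Type-II SS on unbalanced designs)."""
    data = pd.DataFrame({"value": values})
    for name, levels in factors.items():
        data[name] = pd.Categorical(np.asarray(levels).astype(str))
    terms = " * ".join(f"C(Q('{name}'))" for name in factors)
    if subject is not None:
        data["subject"] = pd.Categorical(np.asarray(subject).astype(str))
        formula = f"value ~ C(Q('subject')) + {terms}"
    else:
        formula = f"value ~ {terms}"
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=typ)
    table.index = [_clean_term(t) for t in table.index]
    return table


def srh_test(values: np.ndarray,
             factor_a: np.ndarray,
             factor_b: np.ndarray | None = None,
             tie_correction: bool = True) -> pd.DataFrame:
    """Scheirer-Ray-Hare rank factorial test.

    Returns one row per effect (A, B, A:B) with the rank sum of squares,
    df, H and its chi-square p value.  With ``factor_b`` absent (or
    single-level) the test degenerates to Kruskal-Wallis on ``factor_a``.
    ``tie_correction=False`` uses the no-tie total mean square
    N(N+1)/12 instead of the observed rank variance.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    N = values.size
    if N < 3:
        raise ParameterError("need at least 3 observations")
    ranks = scipy.stats.rankdata(values)
    ss_total = float(((ranks - ranks.mean()) ** 2).sum())
    if ss_total == 0.0:
        raise DesignError("all values tied; rank total mean square is zero")
    ms_total = ss_total / (N - 1) if tie_correction else N * (N + 1) / 12.0
    one_way = factor_b is None or len(np.unique(factor_b)) < 2
    if one_way:
        if len(np.unique(factor_a)) < 2:
            raise DesignError("factor A needs at least 2 levels")
        grand = ranks.mean()
        ss_a = float(sum(
            (ranks[factor_a == g]).size * ((ranks[factor_a == g]).mean() - grand) ** 2
            for g in np.unique(factor_a)))
        rows = [("A", float(len(np.unique(factor_a)) - 1), ss_a)]
    else:
        factor_b = np.asarray(factor_b)
        table = _anova_sums(ranks, {"A": factor_a, "B": factor_b})
        rows = [(eff, float(table.loc[eff, "df"]),
                 float(table.loc[eff, "sum_sq"]))
                for eff in ("A", "B", "A:B") if eff in table.index]
    out = []
    for effect, df, ss in rows:
        h = ss / ms_total
        out.append({"effect": effect, "df": df, "ss_rank": ss, "H": h,
                    "p": float(scipy.stats.chi2.sf(h, df))})
    return pd.DataFrame(out)


def mixed_anova(data: pd.DataFrame, dv: str, factors: list[str],
                subject: str | None = None, typ: int = 2) -> pd.DataFrame:
    """Factorial ANOVA on trial-level data with subject as a random block.

    F tests for all main effects and interactions of ``factors``; when
    ``subject`` is given it enters as an additive blocking factor, so
    the residual denominator df reflects the trial-level sample size.
    Type-II sums of squares handle the unbalanced cells that a 75%-stim
    design produces (identical to the exact decomposition when the
    design is balanced).
    """
    if not factors:
        raise ParameterError("need at least one factor")
    sub = None
    if subject is not None:
        for f in factors:
            if data.groupby(subject)[f].nunique().max() == 1:
                raise DesignError(
                    f"factor {f!r} is constant within every subject; "
                    "confounded with the subject block")
        sub = data[subject].to_numpy()
    table = _anova_sums(data[dv].to_numpy(),
                        {f: data[f].to_numpy() for f in factors},
                        subject=sub, typ=typ)
    df_resid = float(table.loc["Residual", "df"])
    rows = []
    for term in table.index:
        if term in ("Residual", "subject"):
            continue
        rows.append({"effect": term, "df": float(table.loc[term, "df"]),
                     "df_resid": df_resid,
                     "ss": float(table.loc[term, "sum_sq"]),
                     "F": float(table.loc[term, "F"]),
                     "p": float(table.loc[term, "PR(>F)"])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def behavioral_accuracy(trial_table: pd.DataFrame,
                        by: tuple[str, ...] = ("reward", "trial_type")
                        ) -> pd.DataFrame:
    """Percent correct per participant and condition, misses excluded.

    ``pct_correct = correct / (correct + incorrect) * 100``; cells where
    every response was missed are absent from the output.
    """
    if "response" not in trial_table.columns:
        raise ParameterError("trial table has no response column")
    answered = trial_table[trial_table["response"].isin(("correct",
                                                         "incorrect"))]
    keys = ["subject", *by] if "subject" in trial_table.columns else list(by)
    grouped = (answered.assign(correct=answered["response"] == "correct")
               .groupby(keys)
               .agg(pct_correct=("correct", lambda c: 100.0 * c.mean()),
                    n_answered=("correct", "size"))
               .reset_index())
    return grouped


# ---------------------------------------------------------------------------
# Dissociation report
# ---------------------------------------------------------------------------

def _paired_rows(wide: pd.DataFrame, label: str, alpha: float,
                 n_boot: int, seed: int) -> list[dict]:
    """Paired high-vs-low rows from a subject x {high, low} frame."""
    wide = wide.dropna()
    rows = []
    for res in paired_comparison(wide["high"].to_numpy(),
                                 wide["low"].to_numpy(),
                                 alpha=alpha, n_boot=n_boot,
                                 seed=seed).values():
        row = res.to_row()
        row["analysis"] = label
        rows.append(row)
    return rows


def _pivot(df: pd.DataFrame, value: str, column: str = "reward"
           ) -> pd.DataFrame:
    return df.pivot_table(index="subject", columns=column, values=value,
                          aggfunc="mean")


def dissociation_report(amplitudes: pd.DataFrame,
                        bootstrap: BootstrapResult | None = None,
                        alpha: float = 0.05,
                        n_boot: int = 10000,
                        seed: int = 0) -> pd.DataFrame:
    """Assemble the full dissociation statistics table.

    ``amplitudes`` is the trial-level table with a ``subject`` column.
    Rows cover: the reward effect on per-participant mean null- and
    stim-trial amplitudes (paired t / Wilcoxon / Shapiro, repeated on
    the per-trial SD measure as a regression-free robustness check);
    reward x contrast, reward x spatial-frequency and contrast x
    spatial-frequency factorials on trial-level stim amplitudes (mixed
    ANOVA and SRH), plus the three-way mixed ANOVA; behavioral accuracy
    comparisons; and, when supplied, the split-bootstrap p values.
    """
    if "subject" not in amplitudes.columns:
        raise ParameterError("amplitude table needs a subject column")
    from .amplitude import participant_means  # local to avoid cycle
    rows: list[dict] = []
    pm = participant_means(amplitudes)
    if len(pm["subject"].unique()) < 3:
        raise ParameterError("need at least 3 participants for group tests")

    for trial_type in ("null", "stim"):
        sub = pm[pm["trial_type"] == trial_type]
        for value, tag in (("beta", "beta"), ("sd_measure", "sd")):
            rows += _paired_rows(_pivot(sub, value),
                                 f"{trial_type}_{tag}_reward", alpha,
                                 n_boot, seed)

    stim = amplitudes[amplitudes["trial_type"] == "stim"]
    factor_pairs = [("reward", "contrast"), ("reward", "spatial_frequency"),
                    ("contrast", "spatial_frequency")]
    for fa, fb in factor_pairs:
        label = f"stim_beta[{fa}x{fb}]"
        an = mixed_anova(stim, "beta", [fa, fb], subject="subject")
        for _, r in an.iterrows():
            rows.append({"analysis": label, "method": "mixed_anova",
                         "statistic": r["F"], "df": r["df"], "p": r["p"],
                         "note": f"effect={r['effect']} "
                                 f"df_resid={r['df_resid']:.0f}",
                         "n": len(stim)})
        srh = srh_test(stim["beta"].to_numpy(), stim[fa].to_numpy(),
                       stim[fb].to_numpy())
        for _, r in srh.iterrows():
            effect = (r["effect"].replace("A", fa).replace("B", fb)
                      if r["effect"] != "A:B" else f"{fa}:{fb}")
            rows.append({"analysis": label, "method": "srh",
                         "statistic": r["H"], "df": r["df"], "p": r["p"],
                         "note": f"effect={effect}", "n": len(stim)})
    an3 = mixed_anova(stim, "beta",
                      ["spatial_frequency", "contrast", "reward"],
                      subject="subject")
    for _, r in an3.iterrows():
        rows.append({"analysis": "stim_beta[sf x contrast x reward]",
                     "method": "mixed_anova_3way", "statistic": r["F"],
                     "df": r["df"], "p": r["p"],
                     "note": f"effect={r['effect']} "
                             f"df_resid={r['df_resid']:.0f}",
                     "n": len(stim)})

    if "response" in amplitudes.columns:
        acc = behavioral_accuracy(amplitudes)
        rows += _paired_rows(_pivot(acc, "pct_correct", "reward"),
                             "accuracy_reward", alpha, n_boot, seed)
        rows += _paired_rows(
            _pivot(acc, "pct_correct", "trial_type")
            .rename(columns={"stim": "high", "null": "low"}),
            "accuracy_stim_vs_null", alpha, n_boot, seed)

    if bootstrap is not None and bootstrap.p_value is not None:
        for kind, p in bootstrap.p_value.items():
            rows.append({"analysis": f"bootstrap_{kind}",
                         "method": "pseudo_split_bootstrap", "p": p,
                         "estimate": (bootstrap.actual_diff or {}).get(kind),
                         "n": bootstrap.n_iter})

    report = pd.DataFrame(rows)
    lead = ["analysis", "method", "statistic", "df", "p", "estimate",
            "ci_lo", "ci_hi", "n", "note"]
    return report[[c for c in lead if c in report.columns]]
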