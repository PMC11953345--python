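"""Behavioral summary measures and their statistical battery.

Per-subject reaction-time and accuracy summaries of the 2x2 (GO/NOGO x
compatible/incompatible) design, paired t-tests with the paired-design
effect size d_z = |t|/sqrt(n), a 2x2 repeated-measures ANOVA by explicit
within-subject sums-of-squares decomposition with partial eta squared, and
Bonferroni alpha adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DESIGN_CELLS


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a single statistical test."""

    name: str
    statistic: float
    df: tuple[int, ...]
    p: float
    effect_size: float
    effect_name: str = "d"
    alpha_used: float = 0.05

    def as_row(self) -> dict:
        df1 = self.df[0]
        df2 = self.df[1] if len(self.df) > 1 else np.nan
        return {"test": self.name, "statistic": self.statistic,
                "df1": df1, "df2": df2, "p": self.p,
                "effect": self.effect_size, "effect_name": self.effect_name,
                "alpha": self.alpha_used}


def summarize_behavior(log: pd.DataFrame,
                       correct_rt_only: bool = True) -> pd.DataFrame:
    """Per-subject behavioral summary of a trial log.

    Returns one row per subject with mean GO RT per compatibility (over
    correct GO responses only, unless ``correct_rt_only=False``), GO hit
    rates (%), and NOGO correct-rejection rates (%, fraction of NOGO trials
    with response "none").

    Raises ``ValueError`` naming the subject and cell if any of the four
    design cells is empty for some subject.
    """
    out = []
    for subject, g in log.groupby("subject", sort=True):
        row = {"subject": subject}
        for cond, compat in DESIGN_CELLS:
            cell = g[(g.condition == cond) & (g.compatibility == compat)]
            if len(cell) == 0:
                raise ValueError(
                    f"subject {subject} has no trials in cell "
                    f"({cond}, {compat})")
            if cond == "GO":
                rts = cell[cell.correct] if correct_rt_only else cell
                rts = rts.rt_ms.dropna()
                row[f"rt_go_{compat}"] = float(rts.mean()) if len(rts) else np.nan
                row[f"hit_rate_{compat}"] = 100.0 * cell.correct.mean()
            else:
                cr = (cell.response == "none").mean()
                row[f"cr_rate_{compat}"] = 100.0 * cr
        out.append(row)
    return pd.DataFrame(out)


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d_z = |t| / sqrt(n) for n pairs."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return abs(t) / np.sqrt(n)


def paired_t(x, y, name: str = "paired_t", alpha: float = 0.05) -> TestResult:
    """Two-sided paired t-test with df = n-1 and d_z = |t|/sqrt(n).

    Raises on zero variance of the pairwise differences (t undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    return TestResult(name, t, (n - 1,), float(res.pvalue),
                      cohens_d_from_t(t, n), "d", alpha)


def partial_eta_squared(F: float, df_error: int) -> float:
    """partial eta^2 = F / (F + df_error) for a 1-df effect."""
    return F / (F + df_error)


def rm_anova_2x2(table: pd.DataFrame | np.ndarray,
                 factors=("condition", "compatibility")) -> list[TestResult]:
    """2x2 repeated-measures ANOVA by within-subject SS decomposition.

    ``table`` is subjects x 4 cells ordered (A1B1, A1B2, A2B1, A2B2) for
    factors (A, B). Returns F(1, n-1) tests for both main effects and the
    interaction, each with partial eta^2 = SS_effect / (SS_effect + SS_error).

    With two-level factors every effect has 1 df, so each F equals the
    squared paired t on the corresponding contrast scores and no sphericity
    correction can apply (a Greenhouse-Geisser correction is vacuous at two
    levels).
    """
    X = np.asarray(table, float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("table must be subjects x 4 cells")
    if np.isnan(X).any():
        raise ValueError("missing cells in the RM-ANOVA table")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    a1b1, a1b2, a2b1, a2b2 = X.T
    contrasts = {
        factors[0]: (a1b1 + a1b2 - a2b1 - a2b2) / 2,
        factors[1]: (a1b1 - a1b2 + a2b1 - a2b2) / 2,
        f"{factors[0]} x {factors[1]}": (a1b1 - a1b2 - a2b1 + a2b2) / 2,
    }
    results = []
    for name, c in contrasts.items():
        # 1-df effect: SS_effect = n * mean(c)^2, SS_error = SS within c
        ss_eff = n * np.mean(c) ** 2
        ss_err = np.sum((c - np.mean(c)) ** 2)
        if ss_eff == 0:  # identical cells: no effect, F = 0 by convention
            F, eta = 0.0, 0.0
        elif ss_err == 0:
            raise ValueError(f"zero error variance for effect {name!r}")
        else:
            F = ss_eff / (ss_err / (n - 1))
            eta = ss_eff / (ss_eff + ss_err)
        p = float(stats.f.sf(F, 1, n - 1))
        results.append(TestResult(name, float(F), (1, n - 1), p,
                                  float(eta), "partial_eta2"))
    return results


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni correction: family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def run_behavior_battery(log: pd.DataFrame) -> pd.DataFrame:
    """The full behavioral analysis on a trial log, as a tidy results table.

    Paired t on GO RT (compatible vs incompatible); 2x2 RM-ANOVA on accuracy
    (GO hit rate / NOGO correct rejection rate); Bonferroni-corrected
    post-hoc paired t's on accuracy within GO and within NOGO.
    """
    summ = summarize_behavior(log)
    results = [paired_t(summ.rt_go_compatible, summ.rt_go_incompatible,
                        "rt_go_compatible_vs_incompatible")]
    acc = summ[["hit_rate_compatible", "hit_rate_incompatible",
                "cr_rate_compatible", "cr_rate_incompatible"]]
    results += rm_anova_2x2(acc.to_numpy())
    post_alpha = bonferroni_alpha(0.05, 2)
    results.append(paired_t(summ.hit_rate_compatible,
                            summ.hit_rate_incompatible,
                            "accuracy_go_compatible_vs_incompatible",
                            alpha=post_alpha))
    results.append(paired_t(summ.cr_rate_compatible,
                            summ.cr_rate_incompatible,
                            "accuracy_nogo_compatible_vs_incompatible",
                            alpha=post_alpha))
    return pd.DataFrame([r.as_row() for r in results])
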