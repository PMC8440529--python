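"""Dichotomization, log-rank / Kaplan-Meier / Cox analyses, Table-style summaries.

Heterogeneity metrics are dichotomized either at the best cutoff (the
maximally selected log-rank statistic, scanning observed values between
quantile guards so neither group is degenerate) or, for TMB, at an
upper quantile of the cohort (default 0.75, linear-interpolation
quantile). The two-group log-rank statistic is computed in-repo; Cox
proportional-hazards fits delegate partial-likelihood maximization to
lifelines. The best-cutoff procedure inherits the usual selection-bias
caveat of maximally selected statistics; no correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrith")

__all__ = [
    "SurvivalResult",
    "best_cutoff_dichotomize",
    "upper_quantile_dichotomize",
    "logrank_test",
    "cox_fit",
    "km_plot",
    "cohort_summary",
    "spearman",
]


@dataclass(frozen=True)
class SurvivalResult:
    """A dichotomized or Cox survival analysis result."""

    endpoint: str  # DFS | OS
    covariate: str
    cutoff: float | None
    group_sizes: tuple
    chi_square: float | None
    p_logrank: float | None
    hazard_ratio: float | None
    hr_ci: tuple | None
    p_cox: float | None
    adjusted: bool = False
    converged: bool = True
    note: str = ""


def logrank_test(groups, times, events) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` is a binary label per subject. Returns (chi_square, p)
    with p from the chi-square(1) reference distribution.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("logrank_test needs exactly two non-empty groups")
    g1 = groups == labels[1]
    event_times = np.unique(times[events])
    obs1 = 0.0
    exp1 = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = (obs1 - exp1) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def best_cutoff_dichotomize(
    values, times, events, min_group_frac: float = 0.2
) -> tuple[float, np.ndarray]:
    """Best-cutoff dichotomization by maximally selected log-rank statistic.

    Candidate cutoffs are the observed values between the
    ``min_group_frac`` and ``1 - min_group_frac`` quantiles; the cutoff
    maximizing the log-rank chi-square is returned (ties break toward
    the smaller cutoff). Group label is True for value > cutoff.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(values) < 10:
        raise ValueError("need >= 10 analyzable records")
    if np.all(values == values[0]):
        raise ValueError("no valid cutoff: values are constant")
    lo = np.quantile(values, min_group_frac)
    hi = np.quantile(values, 1.0 - min_group_frac)
    candidates = np.unique(values[(values >= lo) & (values <= hi)])
    # a candidate must split off non-empty groups
    candidates = np.array([c for c in candidates if (values > c).any() and (values <= c).any()])
    if len(candidates) == 0:
        raise ValueError("no valid cutoff: no candidates between quantile guards")
    best_c = None
    best_chi = -1.0
    for c in candidates:
        chi, _ = logrank_test(values > c, times, events)
        if chi > best_chi + 1e-12:
            best_chi = chi
            best_c = c
    return float(best_c), values > best_c


def upper_quantile_dichotomize(values, q: float = 0.75) -> np.ndarray:
    """High iff value >= the q-quantile (linear interpolation, type 7)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    cut = np.quantile(values, q)  # numpy default = type-7 linear interpolation
    return values >= cut


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate: str,
    adjusters: tuple = (),
    endpoint: str = "OS",
) -> SurvivalResult:
    """Cox proportional-hazards fit via lifelines.

    Reports the hazard ratio of ``covariate`` with 95% CI, optionally
    adjusted for ``adjusters``. Non-convergence or separation yields a
    flagged (converged=False) result rather than an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = [duration_col, event_col, covariate, *adjusters]
    data = df[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events == 0 or n_events < 1 + len(adjusters):
        return SurvivalResult(
            endpoint=endpoint, covariate=covariate, cutoff=None,
            group_sizes=(len(data),), chi_square=None, p_logrank=None,
            hazard_ratio=None, hr_ci=None, p_cox=None,
            adjusted=bool(adjusters), converged=False,
            note="non-estimable: too few events",
        )
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return SurvivalResult(
            endpoint=endpoint, covariate=covariate, cutoff=None,
            group_sizes=(len(data),), chi_square=None, p_logrank=None,
            hazard_ratio=None, hr_ci=None, p_cox=None,
            adjusted=bool(adjusters), converged=False, note=str(exc),
        )
    hr = float(np.exp(cph.params_[covariate]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.loc[covariate].iloc[0]))
    hi = float(np.exp(ci.loc[covariate].iloc[1]))
    return SurvivalResult(
        endpoint=endpoint,
        covariate=covariate,
        cutoff=None,
        group_sizes=(len(data),),
        chi_square=None,
        p_logrank=None,
        hazard_ratio=hr,
        hr_ci=(lo, hi),
        p_cox=float(cph.summary.loc[covariate, "p"]),
        adjusted=bool(adjusters),
        converged=True,
    )


def km_plot(groups, times, events, path, title: str = "") -> None:
    """Kaplan-Meier curves for two groups, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label in np.unique(groups):
        m = groups == label
        KaplanMeierFitter().fit(
            np.asarray(times)[m], np.asarray(events)[m], label=str(label)
        ).plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (thin wrapper, scipy)."""
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def cohort_summary(records) -> pd.DataFrame:
    """Descriptive cohort table stratified by histology.

    One row per (characteristic, category) with counts and percentages
    for the total cohort and each histology stratum, plus medians with
    ranges for age and tumor size. Percentages are within-characteristic
    (they sum to 100 up to rounding).
    """
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "smoking": r.smoking,
                "stage": r.stage,
                "tumor_size": r.tumor_size,
                "histology": r.histology,
                "treatment_after_surgery": r.treatment_after_surgery,
                "dead": bool(r.os_event),
                "egfr_classic": bool(r.egfr_classic),
            }
            for r in records
        ]
    )
    strata = {"Total": df}
    for h in ("P-SCLC", "C-SCLC"):
        strata[h] = df[df["histology"] == h]

    rows = []

    def add_median(char, col):
        row = {"characteristic": char, "category": "median (range)"}
        for name, sub in strata.items():
            if len(sub):
                row[f"{name}_value"] = (
                    f"{sub[col].median():g} ({sub[col].min():g}-{sub[col].max():g})"
                )
            else:
                row[f"{name}_value"] = "NA"
        rows.append(row)

    def add_counts(char, col, categories):
        for cat in categories:
            row = {"characteristic": char, "category": str(cat)}
            for name, sub in strata.items():
                n = len(sub)
                cnt = int((sub[col] == cat).sum()) if n else 0
                row[f"{name}_n"] = cnt
                row[f"{name}_pct"] = 100.0 * cnt / n if n else 0.0
            rows.append(row)

    add_median("Age (years)", "age")
    add_counts("Sex", "sex", ("male", "female"))
    add_counts("Smoking", "smoking", ("non-smoker", "smoker", "NA"))
    add_median("Tumor size (mm)", "tumor_size")
    add_counts("Stage", "stage", ("I", "II", "III", "IV"))
    add_counts("Treatment after surgery", "treatment_after_surgery", (True, False))
    add_counts("Status", "dead", (False, True))
    add_counts("Classic EGFR mutation", "egfr_classic", (True, False))
    out = pd.DataFrame(rows)
    logger.info("cohort_summary: %d patients", len(df))
    return out
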