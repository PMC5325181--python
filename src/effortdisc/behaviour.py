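"""Behavioural descriptives and control statistics for choice data.

Covers the model-free analyses around the discounting fits: acceptance
proportions by effort and reward level (subject means, group mean +/- SEM),
a per-subject binomial logistic regression of choice on effort, reward and
training reinforcement rate with beta/SE normalisation and group-level
Wilcoxon signed-rank tests, and the signal-detection sensitivity measure
d' = Z(hit rate) - Z(false-alarm rate) used as a performance/risk proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import DOMAINS, effort_code

__all__ = [
    "AcceptanceSummary",
    "RegressionResult",
    "acceptance_by_factor",
    "reinforcement_rates",
    "choice_logistic_regression",
    "d_prime",
    "rt_summary",
]

COVARIATES = ("effort", "reward", "reinforcement")

# |beta/SE| beyond which a logistic fit is treated as separable/degenerate;
# healthy per-subject normalised statistics are O(1)-O(10)
_MAX_ABS_T = 1e3


@dataclass
class AcceptanceSummary:
    """Group acceptance proportions per (domain, factor level).

    ``table`` columns: domain, level, proportion (mean of per-subject cell
    means), sem (over subjects), n_subjects.  Cells with no usable trials for
    a subject are absent from that subject's mean, never counted as zero.
    """

    factor: str
    table: pd.DataFrame
    per_subject: pd.DataFrame


def _usable(data: pd.DataFrame) -> pd.DataFrame:
    return data[data["choice"].isin(["offer", "baseline"])]


def acceptance_by_factor(data: pd.DataFrame, factor: str) -> AcceptanceSummary:
    """Proportion of offers accepted as a function of effort or reward level.

    Computed per subject and cell first, then averaged over subjects with the
    between-subject SEM, matching how group psychometric curves are reported.
    """
    if factor not in ("effort", "reward"):
        raise ValueError("factor must be 'effort' or 'reward'")
    col = "effort_level" if factor == "effort" else "reward"
    usable = _usable(data)
    if len(usable) == 0:
        raise ValueError("no usable (non-missing) trials")
    accepted = (usable["choice"] == "offer").astype(float)
    per_subject = (
        usable.assign(accepted=accepted)
        .groupby(["subject", "domain", col], observed=True)["accepted"]
        .mean()
        .rename("proportion")
        .reset_index()
    )
    group = (
        per_subject.groupby(["domain", col], observed=True)["proportion"]
        .agg(proportion="mean", sem=lambda x: x.sem(ddof=1), n_subjects="count")
        .reset_index()
        .rename(columns={col: "level"})
    )
    return AcceptanceSummary(factor=factor, table=group, per_subject=per_subject)


def reinforcement_rates(training: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, domain, effort level) proportion of rewarded training trials."""
    return (
        training.groupby(["subject", "domain", "effort_level"], observed=True)["rewarded"]
        .mean()
        .rename("reinforcement")
        .reset_index()
    )


@dataclass
class RegressionResult:
    """Per-subject logistic coefficients and group-level signed-rank tests.

    ``per_subject`` holds one row per subject x domain with coefficients,
    standard errors and normalised statistics t = beta/SE per covariate plus a
    ``flagged`` column for degenerate (separable or zero-variance) fits;
    flagged rows are excluded from the group tests but reported.
    ``group`` has one row per domain x covariate with the median normalised
    statistic, signed-rank Z, p-value and the n entering the test.
    """

    per_subject: pd.DataFrame
    group: pd.DataFrame
    n_flagged: int


def _signed_rank(values: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of ``values`` against zero.

    Returns (Z, p) with Z from the normal approximation of the positive-rank
    sum (signed so that Z > 0 means values tend above zero); p is exact for
    n < 25, normal-approximate otherwise.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return np.nan, np.nan
    ranks = stats.rankdata(np.abs(values))
    t_plus = ranks[values > 0].sum()
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (t_plus - mu) / sigma
    method = "exact" if n < 25 else "approx"
    try:
        p = stats.wilcoxon(values, alternative="two-sided", method=method).pvalue
    except ValueError:  # zero differences force the approximate path
        p = stats.wilcoxon(values, alternative="two-sided", method="approx").pvalue
    return float(z), float(p)


def choice_logistic_regression(
    data: pd.DataFrame, training: pd.DataFrame
) -> RegressionResult:
    """Per-subject, per-domain logistic regression of choice on task covariates.

    Effort (code 0.2-1.0), reward (credits) and the training reinforcement
    rate at the offer's effort level enter simultaneously on their natural
    scales, so they may explain shared variance; coefficients are normalised
    to t = beta/SE(beta) before the group-level two-sided Wilcoxon
    signed-rank test per covariate and domain.  Subjects with separable or
    degenerate fits are flagged and excluded from the group test, never
    silently dropped.
    """
    rates = reinforcement_rates(training)
    usable = _usable(data).merge(
        rates, on=["subject", "domain", "effort_level"], how="left"
    )
    if usable["reinforcement"].isna().any():
        missing = (
            usable.loc[usable["reinforcement"].isna(), ["subject", "domain", "effort_level"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"no training reinforcement rate for cells: {missing}")

    rows = []
    for (subject, domain), grp in usable.groupby(["subject", "domain"], observed=True):
        y = (grp["choice"] == "offer").to_numpy(dtype=float)
        row = {"subject": subject, "domain": domain, "n_trials": len(grp)}
        if y.min() == y.max():
            row.update(flagged=True, flag_reason="single outcome value")
            rows.append(row)
            continue
        covs = pd.DataFrame(
            {
                "effort": effort_code(grp["effort_level"].to_numpy()),
                "reward": grp["reward"].to_numpy(dtype=float),
                "reinforcement": grp["reinforcement"].to_numpy(dtype=float),
            }
        )
        constant = [c for c in COVARIATES if covs[c].nunique() == 1]
        if constant:
            row.update(
                flagged=True,
                flag_reason=f"zero-variance covariate(s): {constant} (degenerate SE)",
            )
            rows.append(row)
            continue
        X = sm.add_constant(covs, has_constant="add")
        flagged, reason = False, ""
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params, bse = fit.params, fit.bse
        except Exception as err:  # singular design, non-convergence
            row.update(flagged=True, flag_reason=f"fit failed: {err}")
            rows.append(row)
            continue
        for cov in COVARIATES:
            b, se = params[cov], bse[cov]
            row[f"coef_{cov}"] = b
            row[f"se_{cov}"] = se
            t = b / se if se > 0 and np.isfinite(se) else np.nan
            row[f"t_{cov}"] = t
            if not np.isfinite(t) or abs(t) > _MAX_ABS_T:
                flagged = True
                reason = f"degenerate estimate for {cov} (complete separation suspected)"
        row["flagged"] = flagged
        row["flag_reason"] = reason
        rows.append(row)

    per_subject = pd.DataFrame(rows)
    clean = per_subject[~per_subject["flagged"]]
    group_rows = []
    for domain in DOMAINS:
        dom = clean[clean["domain"] == domain]
        for cov in COVARIATES:
            t_vals = dom[f"t_{cov}"].to_numpy(dtype=float) if len(dom) else np.array([])
            z, p = _signed_rank(t_vals) if len(t_vals) else (np.nan, np.nan)
            group_rows.append(
                {
                    "domain": domain,
                    "covariate": cov,
                    "n": len(t_vals),
                    "median_t": float(np.median(t_vals)) if len(t_vals) else np.nan,
                    "z": z,
                    "p": p,
                }
            )
    return RegressionResult(
        per_subject=per_subject,
        group=pd.DataFrame(group_rows),
        n_flagged=int(per_subject["flagged"].sum()),
    )


def d_prime(hits: int, misses: int, false_alarms: int, opportunities: int) -> float:
    """Signal-detection sensitivity d' = Z(hit rate) - Z(false-alarm rate).

    ``opportunities`` is the number of chances to commit a false alarm.
    Extreme rates of 0 or 1 are continuity-corrected to 1/(2N) and
    1 - 1/(2N) with that rate's own trial count N, the standard correction
    for finite samples.
    """
    for name, v in (
        ("hits", hits),
        ("misses", misses),
        ("false_alarms", false_alarms),
        ("opportunities", opportunities),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n_signal = hits + misses
    if n_signal == 0:
        raise ValueError("hits + misses must be positive")
    if opportunities == 0:
        raise ValueError("opportunities must be positive")
    if false_alarms > opportunities:
        raise ValueError("false_alarms cannot exceed opportunities")

    def corrected(rate, n):
        lo = 1.0 / (2 * n)
        return min(max(rate, lo), 1.0 - lo)

    hr = corrected(hits / n_signal, n_signal)
    far = corrected(false_alarms / opportunities, opportunities)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def rt_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Per (domain, effort level) reaction-time medians, then group means.

    Cell-level summary only; omnibus repeated-measures testing is left to
    general statistics tools.
    """
    usable = _usable(data).dropna(subset=["rt"])
    per_subject = (
        usable.groupby(["subject", "domain", "effort_level"], observed=True)["rt"]
        .median()
        .rename("median_rt")
        .reset_index()
    )
    return (
        per_subject.groupby(["domain", "effort_level"], observed=True)["median_rt"]
        .agg(mean_median_rt="mean", sem=lambda x: x.sem(ddof=1), n_subjects="count")
        .reset_index()
    )
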