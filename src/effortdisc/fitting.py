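"""Maximum-likelihood fitting of discounting models and AIC/BIC comparison.

Each candidate model is fitted per subject by minimising the negative
log-likelihood of the observed offer-vs-baseline choices with a multi-start
Nelder-Mead simplex search (derivative-free; restarts from random starting
values are the robustness mechanism).  Model fits are compared with AIC
(2*p + 2*NLL) and BIC (p*ln n + 2*NLL), aggregated by summation across
subjects.

Likelihoods for the separate-k/separate-beta class factorise across effort
domains (the cognitive parameters touch only cognitive trials), so those
4-parameter models are fitted exactly as two independent 2-parameter
per-domain problems; ``fit_all_models`` additionally caches the per-domain
solutions across the 16 models of that class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_expit

from .models import (
    BASELINE_SV,
    DOMAINS,
    FAMILIES,
    DiscountModelSpec,
    SharingClass,
    effort_code,
    enumerate_models,
    subjective_value,
)

__all__ = [
    "K_BOUNDS",
    "BETA_BOUNDS",
    "DEFAULT_N_RESTARTS",
    "FitResult",
    "ComparisonTable",
    "negative_log_likelihood",
    "fit_model",
    "fit_all_models",
    "compare_models",
    "difficulty_index",
]

# Search box for the optimiser; points outside are treated as infeasible.
K_BOUNDS = (0.0, 10.0)
BETA_BOUNDS = (0.0, 100.0)

# Starting-value distributions for the random restarts.
K_START = (0.01, 3.0)
BETA_START = (0.5, 20.0)

DEFAULT_N_RESTARTS = 20


@dataclass(frozen=True)
class FitResult:
    """MLE solution for one model on one subject's choices."""

    subject: object
    model: DiscountModelSpec
    params: dict[str, float]
    neg_log_lik: float
    n_trials: int
    n_restarts_converged: int

    @property
    def aic(self) -> float:
        return 2.0 * self.model.n_params + 2.0 * self.neg_log_lik

    @property
    def bic(self) -> float:
        return self.model.n_params * np.log(self.n_trials) + 2.0 * self.neg_log_lik

    def to_row(self) -> dict:
        p = self.params
        return {
            "subject": self.subject,
            "model_id": self.model.model_id,
            "sharing_class": self.model.sharing_class.value,
            "family_cog": self.model.family_cog,
            "family_phys": self.model.family_phys,
            "k_cog": p.get("k_cog", p.get("k")),
            "k_phys": p.get("k_phys", p.get("k")),
            "beta_cog": p.get("beta_cog", p.get("beta")),
            "beta_phys": p.get("beta_phys", p.get("beta")),
            "nll": self.neg_log_lik,
            "n_trials": self.n_trials,
            "aic": self.aic,
            "bic": self.bic,
        }


# ---------------------------------------------------------------------------
# Per-subject trial arrays


class _SubjectData:
    """Per-domain numpy views of one subject's usable (non-missing) trials.

    ``sign`` is +1 where the offer was chosen and -1 for the baseline, so the
    per-trial log-likelihood is log_expit(sign * beta * (SV - 1)).
    """

    def __init__(self, trials: pd.DataFrame):
        trials = trials[trials["choice"] != "missing"]
        if len(trials) == 0:
            raise ValueError("no usable (non-missing) trials for this subject")
        bad_choice = set(trials["choice"].unique()) - {"offer", "baseline"}
        if bad_choice:
            raise ValueError(f"unrecognised choice value(s): {sorted(bad_choice)}")
        bad_dom = set(trials["domain"].unique()) - set(DOMAINS)
        if bad_dom:
            raise ValueError(f"unrecognised domain value(s): {sorted(bad_dom)}")
        self.n_trials = len(trials)
        self.by_domain = {}
        for dom in DOMAINS:
            sub = trials[trials["domain"] == dom]
            self.by_domain[dom] = (
                sub["reward"].to_numpy(dtype=float),
                effort_code(sub["effort_level"].to_numpy()),
                np.where(sub["choice"].to_numpy() == "offer", 1.0, -1.0),
            )


def _domain_nll(R, E, sign, family, k, beta):
    sv = subjective_value(family, R, E, k)
    with np.errstate(over="ignore", invalid="ignore"):
        ll = log_expit(sign * beta * (sv - BASELINE_SV))
    total = -ll.sum()
    return total if np.isfinite(total) else np.inf


def _unpack(params, model):
    """Map the flat parameter vector to (k_cog, k_phys, beta_cog, beta_phys)."""
    cls = model.sharing_class
    if cls is SharingClass.SHARED_K_SHARED_BETA:
        k, beta = params
        return k, k, beta, beta
    if cls is SharingClass.SEPARATE_K_SHARED_BETA:
        kc, kp, beta = params
        return kc, kp, beta, beta
    kc, kp, bc, bp = params
    return kc, kp, bc, bp


def negative_log_likelihood(params, data, model: DiscountModelSpec) -> float:
    """Summed -log p(observed choice) over a subject's non-missing trials.

    ``params`` follows ``model.param_names``.  Points outside the search box
    or producing non-finite intermediates return +inf so an optimiser treats
    them as infeasible.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (model.n_params,):
        raise ValueError(
            f"expected {model.n_params} parameters for {model.model_id}, "
            f"got {params.shape}"
        )
    if not isinstance(data, _SubjectData):
        data = _SubjectData(data)
    kc, kp, bc, bp = _unpack(params, model)
    for k in (kc, kp):
        if not (K_BOUNDS[0] <= k <= K_BOUNDS[1]):
            return np.inf
    for b in (bc, bp):
        if not (BETA_BOUNDS[0] <= b <= BETA_BOUNDS[1]):
            return np.inf
    total = 0.0
    for dom, k, beta, fam in (
        ("cognitive", kc, bc, model.family_cog),
        ("physical", kp, bp, model.family_phys),
    ):
        R, E, sign = data.by_domain[dom]
        if len(R):
            total += _domain_nll(R, E, sign, fam, k, beta)
    return total


# ---------------------------------------------------------------------------
# Optimisation


def _multistart(objective, n_params, n_restarts, rng, xatol, fatol):
    """Best of ``n_restarts`` Nelder-Mead runs from random starting values.

    k-like coordinates come first in the vector, beta-like last; starting
    values are drawn k ~ U(0.01, 3), beta ~ U(0.5, 20).
    """
    n_k = {2: 1, 3: 2, 4: 2}[n_params]
    best = None
    n_converged = 0
    for _ in range(n_restarts):
        x0 = np.concatenate(
            [
                rng.uniform(*K_START, size=n_k),
                rng.uniform(*BETA_START, size=n_params - n_k),
            ]
        )
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": 400 * n_params},
        )
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimisation restarts failed")
    return best, n_converged


def _fit_joint(data, model, n_restarts, seed, xatol, fatol):
    obj = lambda x: negative_log_likelihood(x, data, model)
    rng = np.random.default_rng([seed, 0])
    best, n_conv = _multistart(obj, model.n_params, n_restarts, rng, xatol, fatol)
    return best.x, best.fun, n_conv


def _fit_domain(data, domain, family, n_restarts, seed, xatol, fatol):
    """2-parameter (k, beta) fit on one domain's trials.

    Seeded by (seed, domain index, family index) so the solution is identical
    whether reached through ``fit_model`` or through the ``fit_all_models``
    cache.
    """
    R, E, sign = data.by_domain[domain]

    def obj(x):
        k, beta = x
        if not (K_BOUNDS[0] <= k <= K_BOUNDS[1] and BETA_BOUNDS[0] <= beta <= BETA_BOUNDS[1]):
            return np.inf
        return _domain_nll(R, E, sign, family, k, beta)

    rng = np.random.default_rng([seed, 1 + DOMAINS.index(domain), FAMILIES.index(family)])
    best, n_conv = _multistart(obj, 2, n_restarts, rng, xatol, fatol)
    return best.x, best.fun, n_conv


def fit_model(
    data,
    model: DiscountModelSpec,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    xatol: float = 1e-5,
    fatol: float = 1e-7,
    subject=None,
) -> FitResult:
    """Fit one model to one subject's trials by multi-start maximum likelihood.

    ``data`` is a long-format trial table (columns ``domain``, ``effort_level``,
    ``reward``, ``choice``); missing-choice trials are excluded.  Both domains
    enter one likelihood because the sharing classes couple them.
    Deterministic given ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if not isinstance(data, _SubjectData):
        if subject is None and "subject" in data.columns:
            subs = data["subject"].unique()
            if len(subs) > 1:
                raise ValueError("fit_model expects a single subject's trials")
            subject = subs[0]
        data = _SubjectData(data)
    try:
        if model.sharing_class is SharingClass.SEPARATE_K_SEPARATE_BETA:
            # Exact factorisation: each domain's (k, beta) only enters its
            # own trials' likelihood.
            params, nll, n_conv = {}, 0.0, n_restarts
            for dom, fam, kname, bname in (
                ("cognitive", model.family_cog, "k_cog", "beta_cog"),
                ("physical", model.family_phys, "k_phys", "beta_phys"),
            ):
                x, f, c = _fit_domain(data, dom, fam, n_restarts, seed, xatol, fatol)
                params[kname], params[bname] = float(x[0]), float(x[1])
                nll += f
                n_conv = min(n_conv, c)
        else:
            x, nll, n_conv = _fit_joint(data, model, n_restarts, seed, xatol, fatol)
            params = {name: float(v) for name, v in zip(model.param_names, x)}
    except RuntimeError as err:
        raise RuntimeError(
            f"fitting failed for model {model.model_id}, subject {subject!r}: {err}"
        ) from err
    return FitResult(
        subject=subject,
        model=model,
        params=params,
        neg_log_lik=float(nll),
        n_trials=data.n_trials,
        n_restarts_converged=n_conv,
    )


def fit_all_models(
    data,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    models: list[DiscountModelSpec] | None = None,
    xatol: float = 1e-5,
    fatol: float = 1e-7,
    subject=None,
) -> list[FitResult]:
    """Fit every candidate model (default: all 36) to one subject's trials.

    The 16 separate-k/separate-beta models share 8 per-domain 2-parameter
    solutions (4 families x 2 domains), which are computed once.
    """
    if models is None:
        models = enumerate_models()
    if subject is None and hasattr(data, "columns") and "subject" in data.columns:
        subs = data["subject"].unique()
        if len(subs) > 1:
            raise ValueError("fit_all_models expects a single subject's trials")
        subject = subs[0]
    sdata = data if isinstance(data, _SubjectData) else _SubjectData(data)

    domain_cache: dict[tuple[str, str], tuple] = {}

    def domain_fit(dom, fam):
        key = (dom, fam)
        if key not in domain_cache:
            domain_cache[key] = _fit_domain(sdata, dom, fam, n_restarts, seed, xatol, fatol)
        return domain_cache[key]

    results = []
    for model in models:
        if model.sharing_class is SharingClass.SEPARATE_K_SEPARATE_BETA:
            xc, fc, cc = domain_fit("cognitive", model.family_cog)
            xp, fp, cp = domain_fit("physical", model.family_phys)
            results.append(
                FitResult(
                    subject=subject,
                    model=model,
                    params={
                        "k_cog": float(xc[0]),
                        "beta_cog": float(xc[1]),
                        "k_phys": float(xp[0]),
                        "beta_phys": float(xp[1]),
                    },
                    neg_log_lik=float(fc + fp),
                    n_trials=sdata.n_trials,
                    n_restarts_converged=min(cc, cp),
                )
            )
        else:
            results.append(
                fit_model(sdata, model, n_restarts, seed, xatol, fatol, subject=subject)
            )
    return results


# ---------------------------------------------------------------------------
# Model comparison


@dataclass
class ComparisonTable:
    """Criterion values summed across subjects per model, plus winners.

    ``table`` has one row per model with the summed criterion and per-subject
    winner counts; ``winner`` holds the spec with the minimal summed
    criterion (ties broken toward fewer parameters, then stable enumeration
    order).
    """

    criterion: str
    table: pd.DataFrame
    winner: DiscountModelSpec
    subject_winner_counts: pd.Series = field(repr=False, default=None)


def _enumeration_rank():
    return {m.model_id: i for i, m in enumerate(enumerate_models())}


def compare_models(fits: list[FitResult], criterion: str = "aic") -> ComparisonTable:
    """Aggregate per-subject fits into a group-level model comparison.

    Requires a complete subjects x models grid (every subject fitted with
    every model present in ``fits``).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if not fits:
        raise ValueError("no fits supplied")
    rows = pd.DataFrame(
        {
            "subject": [f.subject for f in fits],
            "model_id": [f.model.model_id for f in fits],
            "value": [getattr(f, criterion) for f in fits],
        }
    )
    grid = rows.pivot_table(index="subject", columns="model_id", values="value")
    if grid.isna().any().any():
        missing = [
            (s, m) for s in grid.index for m in grid.columns if pd.isna(grid.loc[s, m])
        ]
        raise ValueError(f"incomplete fit grid; missing (subject, model): {missing}")

    by_id = {f.model.model_id: f.model for f in fits}
    rank = _enumeration_rank()
    order = sorted(by_id, key=lambda mid: rank.get(mid, len(rank)))

    summed = grid.sum(axis=0)
    per_subject_winner = grid.apply(
        lambda row: min(order, key=lambda mid: (row[mid], by_id[mid].n_params, rank.get(mid, 0))),
        axis=1,
    )
    counts = per_subject_winner.value_counts().reindex(order, fill_value=0)

    table = pd.DataFrame(
        {
            "model_id": order,
            "sharing_class": [by_id[m].sharing_class.value for m in order],
            "family_cog": [by_id[m].family_cog for m in order],
            "family_phys": [by_id[m].family_phys for m in order],
            "n_params": [by_id[m].n_params for m in order],
            criterion: [summed[m] for m in order],
            "n_subject_wins": [int(counts[m]) for m in order],
        }
    )
    winner_id = min(order, key=lambda mid: (summed[mid], by_id[mid].n_params, rank.get(mid, 0)))
    return ComparisonTable(
        criterion=criterion,
        table=table,
        winner=by_id[winner_id],
        subject_winner_counts=counts,
    )


def difficulty_index(p):
    """Decision-difficulty score -|p - 0.5| from a softmax choice probability.

    0 at p = 0.5 (hardest, indifferent) down to -0.5 at p in {0, 1}.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("choice probability must lie in [0, 1]")
    return -np.abs(p - 0.5)
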