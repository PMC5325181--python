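"""Reading and writing the package's tabular interchange formats.

All files are plain UTF-8 CSV with headers.  The choice table is long format,
one row per decision trial; the training table one row per training trial;
fit tables one row per (subject, model).  The regressor export produces the
trial-wise parametric-modulator values (offer-minus-baseline subjective value
difference and softmax decision difficulty) consumed by external GLM tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult, difficulty_index
from .models import (
    DOMAINS,
    OFFER_EFFORT_LEVELS,
    REWARD_LEVELS,
    DiscountModelSpec,
    SharingClass,
    choice_probability,
    effort_code,
    subjective_value,
    sv_difference,
)

__all__ = [
    "read_choices",
    "write_choices",
    "read_training",
    "write_training",
    "fits_to_frame",
    "fits_from_frame",
    "write_fits",
    "read_fits",
    "build_regressors",
]

CHOICE_COLUMNS = ["subject", "domain", "effort_level", "reward", "choice"]
CHOICE_VALUES = {"offer", "baseline", "missing"}


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def validate_choices(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CHOICE_COLUMNS, "choice table")
    bad_dom = set(df["domain"].unique()) - set(DOMAINS)
    if bad_dom:
        raise ValueError(f"invalid domain value(s): {sorted(bad_dom)}")
    bad_choice = set(df["choice"].unique()) - CHOICE_VALUES
    if bad_choice:
        raise ValueError(f"invalid choice value(s): {sorted(bad_choice)}")
    bad_rew = set(df["reward"].unique()) - set(REWARD_LEVELS)
    if bad_rew:
        raise ValueError(
            f"invalid reward value(s): {sorted(bad_rew)}; permitted: {REWARD_LEVELS}"
        )
    bad_lev = set(df["effort_level"].unique()) - set(OFFER_EFFORT_LEVELS)
    if bad_lev:
        raise ValueError(
            f"invalid offer effort level(s): {sorted(bad_lev)}; offers use levels 2-6"
        )
    return df


def read_choices(path) -> pd.DataFrame:
    """Read and validate a long-format choice CSV."""
    return validate_choices(pd.read_csv(path))


def write_choices(df: pd.DataFrame, path) -> None:
    validate_choices(df)
    df.to_csv(path, index=False)


def read_training(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["subject", "domain", "effort_level", "rewarded"], "training table"
    )
    return df


def write_training(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fits])


def fits_from_frame(df: pd.DataFrame) -> list[FitResult]:
    """Rebuild FitResult objects from a fit table (inverse of fits_to_frame)."""
    _require_columns(
        df,
        ["subject", "sharing_class", "family_cog", "family_phys", "nll", "n_trials"],
        "fit table",
    )
    fits = []
    for _, r in df.iterrows():
        model = DiscountModelSpec(
            SharingClass(r["sharing_class"]), r["family_cog"], r["family_phys"]
        )
        if model.sharing_class is SharingClass.SHARED_K_SHARED_BETA:
            params = {"k": r["k_cog"], "beta": r["beta_cog"]}
        elif model.sharing_class is SharingClass.SEPARATE_K_SHARED_BETA:
            params = {"k_cog": r["k_cog"], "k_phys": r["k_phys"], "beta": r["beta_cog"]}
        else:
            params = {
                "k_cog": r["k_cog"],
                "k_phys": r["k_phys"],
                "beta_cog": r["beta_cog"],
                "beta_phys": r["beta_phys"],
            }
        fits.append(
            FitResult(
                subject=r["subject"],
                model=model,
                params={k: float(v) for k, v in params.items()},
                neg_log_lik=float(r["nll"]),
                n_trials=int(r["n_trials"]),
                n_restarts_converged=int(r.get("n_restarts_converged", 0)),
            )
        )
    return fits


def write_fits(fits: list[FitResult], path) -> None:
    fits_to_frame(fits).to_csv(path, index=False)


def read_fits(path) -> list[FitResult]:
    return fits_from_frame(pd.read_csv(path))


def build_regressors(
    choices: pd.DataFrame, fits_by_subject: dict[object, FitResult]
) -> pd.DataFrame:
    """Trial-wise parametric-modulator table from choices plus fitted models.

    For each non-missing trial, computes the offer's subjective value under
    the subject's fitted model for that domain, the offer-minus-baseline
    value difference, and the decision difficulty -|p - 0.5| from the fitted
    softmax.  Requires an ``onset_s`` column (present in simulated
    schedules) for time-locking by external GLM tools.
    """
    _require_columns(choices, CHOICE_COLUMNS + ["onset_s"], "choice table")
    rows = []
    for subject, grp in choices.groupby("subject", observed=True):
        if subject not in fits_by_subject:
            raise ValueError(f"no fitted parameters supplied for subject {subject!r}")
        fit = fits_by_subject[subject]
        p = fit.params
        for dom, fam in (
            ("cognitive", fit.model.family_cog),
            ("physical", fit.model.family_phys),
        ):
            sub = grp[(grp["domain"] == dom) & (grp["choice"] != "missing")]
            if len(sub) == 0:
                continue
            k = p.get("k_cog" if dom == "cognitive" else "k_phys", p.get("k"))
            beta = p.get("beta_cog" if dom == "cognitive" else "beta_phys", p.get("beta"))
            E = effort_code(sub["effort_level"].to_numpy())
            R = sub["reward"].to_numpy(dtype=float)
            svd = sv_difference(fam, R, E, k)
            prob = choice_probability(svd + 1.0, beta)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "domain": dom,
                        "trial_index": sub["trial_index"].to_numpy()
                        if "trial_index" in sub
                        else np.arange(1, len(sub) + 1),
                        "onset_s": sub["onset_s"].to_numpy(),
                        "sv_difference": svd,
                        "difficulty": difficulty_index(prob),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subject", "onset_s"], ignore_index=True)
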