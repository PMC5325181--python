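"""Subjective-value functions, softmax choice rule, and the candidate model space.

The task offers a high-effort/high-reward option ("offer": effort level 2-6,
reward 2-10 credits) against a fixed low-effort/low-reward "baseline" (effort
level 1, 1 credit) whose subjective value is defined as 1.  An offer's
subjective value SV is its reward R devalued by the dimensionless effort code
E in {0.2, ..., 1.0} through one of four discounting families:

    linear       SV = R * (1 - k * E)
    hyperbolic   SV = R / (1 + k * E)
    parabolic    SV = R - k * E**2
    exponential  SV = R * exp(-k * E)

The probability of choosing the offer over the baseline follows a softmax with
stochasticity parameter beta:

    Pr(offer) = exp(beta * SV) / (exp(beta * 1) + exp(beta * SV))

Candidate models combine a family per effort domain (cognitive, physical) with
one of three parameter-sharing classes, giving 4 + 16 + 16 = 36 models.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "FAMILIES",
    "DOMAINS",
    "REWARD_LEVELS",
    "OFFER_EFFORT_LEVELS",
    "BASELINE_SV",
    "SharingClass",
    "DiscountModelSpec",
    "effort_code",
    "subjective_value",
    "choice_probability",
    "enumerate_models",
    "sv_difference",
]

FAMILIES = ("linear", "hyperbolic", "parabolic", "exponential")
DOMAINS = ("cognitive", "physical")
REWARD_LEVELS = (2, 4, 6, 8, 10)
OFFER_EFFORT_LEVELS = (2, 3, 4, 5, 6)

#: Subjective value of the fixed baseline option (1 credit at effort level 1).
BASELINE_SV = 1.0


class SharingClass(str, enum.Enum):
    """How discount (k) and softmax (beta) parameters are shared across domains."""

    SHARED_K_SHARED_BETA = "shared_k_shared_beta"
    SEPARATE_K_SHARED_BETA = "separate_k_shared_beta"
    SEPARATE_K_SEPARATE_BETA = "separate_k_separate_beta"


_N_PARAMS = {
    SharingClass.SHARED_K_SHARED_BETA: 2,
    SharingClass.SEPARATE_K_SHARED_BETA: 3,
    SharingClass.SEPARATE_K_SEPARATE_BETA: 4,
}


@dataclass(frozen=True)
class DiscountModelSpec:
    """One of the 36 candidate models: a family per domain plus a sharing class.

    ``n_params`` counts free parameters: 2 (k, beta), 3 (k_cog, k_phys, beta)
    or 4 (k_cog, k_phys, beta_cog, beta_phys).
    """

    sharing_class: SharingClass
    family_cog: str
    family_phys: str

    def __post_init__(self) -> None:
        for fam in (self.family_cog, self.family_phys):
            if fam not in FAMILIES:
                raise ValueError(
                    f"unknown discounting family {fam!r}; valid families: {FAMILIES}"
                )
        if (
            self.sharing_class is SharingClass.SHARED_K_SHARED_BETA
            and self.family_cog != self.family_phys
        ):
            raise ValueError(
                "shared_k_shared_beta requires the same family in both domains"
            )

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.sharing_class]

    @property
    def model_id(self) -> str:
        tag = {
            SharingClass.SHARED_K_SHARED_BETA: "shared",
            SharingClass.SEPARATE_K_SHARED_BETA: "sepk",
            SharingClass.SEPARATE_K_SEPARATE_BETA: "sepkb",
        }[self.sharing_class]
        return f"{tag}:{self.family_cog}/{self.family_phys}"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.sharing_class is SharingClass.SHARED_K_SHARED_BETA:
            return ("k", "beta")
        if self.sharing_class is SharingClass.SEPARATE_K_SHARED_BETA:
            return ("k_cog", "k_phys", "beta")
        return ("k_cog", "k_phys", "beta_cog", "beta_phys")


def effort_code(level):
    """Map an offer effort level (integer 2-6) to its dimensionless code E.

    The five offer levels map monotonically onto the code set
    {0.2, 0.4, 0.6, 0.8, 1.0} via E = (level - 1) / 5.
    """
    level = np.asarray(level)
    if not np.all(np.isin(level, OFFER_EFFORT_LEVELS)):
        bad = np.unique(level[~np.isin(level, OFFER_EFFORT_LEVELS)])
        raise ValueError(
            f"offer effort level(s) {bad.tolist()} outside the permitted range 2-6"
        )
    return (level - 1) / 5.0


def subjective_value(family: str, R, E, k):
    """Subjective value of an offer of reward ``R`` at effort code ``E``.

    ``k`` is the subject-specific discount parameter (higher k = steeper
    devaluation).  Negative values are legal outputs for the linear and
    parabolic families and are never clipped.  Accepts scalars or arrays.
    """
    R = np.asarray(R, dtype=float)
    E = np.asarray(E, dtype=float)
    if family == "linear":
        return R * (1.0 - k * E)
    if family == "hyperbolic":
        return R / (1.0 + k * E)
    if family == "parabolic":
        return R - k * E**2
    if family == "exponential":
        return R * np.exp(-k * E)
    raise ValueError(
        f"unknown discounting family {family!r}; valid families: {FAMILIES}"
    )


def choice_probability(sv_offer, beta):
    """Softmax probability of choosing the offer over the unit-value baseline.

    Pr(offer) = e^(beta*SV) / (e^beta + e^(beta*SV)), computed as a logistic
    of beta * (SV - 1) so that large exponents cannot overflow.
    """
    sv_offer = np.asarray(sv_offer, dtype=float)
    if not np.all(np.isfinite(sv_offer)):
        raise ValueError("sv_offer must be finite")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return expit(beta * (sv_offer - BASELINE_SV))


def enumerate_models() -> list[DiscountModelSpec]:
    """Enumerate the full 36-model space in a deterministic, stable order.

    4 shared-k/shared-beta models (one per family), then 16
    separate-k/shared-beta (all family pairs, cognitive family outermost),
    then 16 separate-k/separate-beta.
    """
    specs = [
        DiscountModelSpec(SharingClass.SHARED_K_SHARED_BETA, fam, fam)
        for fam in FAMILIES
    ]
    for cls in (SharingClass.SEPARATE_K_SHARED_BETA, SharingClass.SEPARATE_K_SEPARATE_BETA):
        specs.extend(
            DiscountModelSpec(cls, fc, fp) for fc in FAMILIES for fp in FAMILIES
        )
    return specs


def sv_difference(family: str, R, E, k):
    """Offer-minus-baseline value difference, SV(offer) - 1.

    This is the trial-wise quantity exported as a parametric value regressor
    for external GLM tools.
    """
    return subjective_value(family, R, E, k) - BASELINE_SV
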