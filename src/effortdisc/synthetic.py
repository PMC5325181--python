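"""Synthetic task schedules, choice data, and training-session performance.

Emulates the scanner task: one run of 150 offer-vs-baseline decisions (75
cognitive + 75 physical, randomly interleaved), each offer drawn from the
5 effort levels (2-6) x 5 reward levels (2-10 credits) factorial with each
cell appearing 3 times per domain.  Choices are Bernoulli draws from the
softmax of the subjective value under known ground-truth parameters, which
makes every downstream stage (fitting, comparison, behavioural statistics)
verifiable by parameter and model recovery without any real subject data.

Also simulates the pre-scan training block (10 trials per effort level 1-6
per domain) whose per-level reward rates feed the reinforcement covariate of
the behavioural logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import BETA_BOUNDS, K_BOUNDS
from .models import (
    DOMAINS,
    OFFER_EFFORT_LEVELS,
    REWARD_LEVELS,
    DiscountModelSpec,
    SharingClass,
    choice_probability,
    effort_code,
    subjective_value,
)

__all__ = [
    "GroundTruth",
    "generate_schedule",
    "simulate_choices",
    "simulate_training",
    "simulate_cohort",
]

# Task timing constants (seconds): offer cue, jitter range, choice window.
OFFER_DURATION = 3.0
JITTER_RANGE = (2.0, 4.0)
CHOICE_DURATION = 2.4

TRAINING_EFFORT_LEVELS = (1, 2, 3, 4, 5, 6)
TRAINING_TRIALS_PER_LEVEL = 10

#: Default per-level training success probability (task reinforces > 80%).
DEFAULT_TRAINING_SUCCESS = 0.85


def _default_training_probs():
    return {
        dom: {lev: DEFAULT_TRAINING_SUCCESS for lev in TRAINING_EFFORT_LEVELS}
        for dom in DOMAINS
    }


@dataclass
class GroundTruth:
    """Generating model and parameters for one simulated subject."""

    subject: object
    model: DiscountModelSpec
    k_cog: float
    k_phys: float
    beta_cog: float
    beta_phys: float
    #: per-domain, per-effort-level probability of a rewarded training trial
    training_success: dict = field(default_factory=_default_training_probs)
    #: probability that a choice trial gets no response (recorded as missing)
    missing_rate: float = 0.0

    def __post_init__(self):
        for name, v, bounds in (
            ("k_cog", self.k_cog, K_BOUNDS),
            ("k_phys", self.k_phys, K_BOUNDS),
            ("beta_cog", self.beta_cog, BETA_BOUNDS),
            ("beta_phys", self.beta_phys, BETA_BOUNDS),
        ):
            if not (bounds[0] <= v <= bounds[1]):
                raise ValueError(f"{name}={v} outside the fitting bounds {bounds}")
        for dom, probs in self.training_success.items():
            for lev, p in probs.items():
                if not (0 < p <= 1):
                    raise ValueError(
                        f"training success probability {p} for {dom} level {lev} "
                        "must lie in (0, 1]"
                    )
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    def domain_params(self, domain: str):
        """(family, k, beta) generating the given domain's choices."""
        if domain == "cognitive":
            return self.model.family_cog, self.k_cog, self.beta_cog
        if domain == "physical":
            return self.model.family_phys, self.k_phys, self.beta_phys
        raise ValueError(f"unknown domain {domain!r}")


def generate_schedule(n_per_domain: int = 75, seed: int = 0) -> pd.DataFrame:
    """Balanced, randomly interleaved offer schedule with realistic onsets.

    Each domain contains ``n_per_domain / 25`` repetitions of the full
    5 effort x 5 reward factorial; the two domains' trials are interleaved by
    a seeded permutation.  Offer-cue onsets accumulate the task's timing:
    3 s offer, 2-4 s jitter, 2.4 s choice window, 2-4 s inter-trial jitter.
    """
    if n_per_domain <= 0 or n_per_domain % 25 != 0:
        raise ValueError(
            f"n_per_domain must be a positive multiple of 25 (got {n_per_domain}); "
            "the 5x5 effort-reward factorial cannot be balanced otherwise"
        )
    reps = n_per_domain // 25
    rng = np.random.default_rng(seed)
    cells = [
        (dom, lev, rew)
        for dom in DOMAINS
        for lev in OFFER_EFFORT_LEVELS
        for rew in REWARD_LEVELS
        for _ in range(reps)
    ]
    order = rng.permutation(len(cells))
    n = len(cells)
    pre_jitter = rng.uniform(*JITTER_RANGE, size=n)
    iti_jitter = rng.uniform(*JITTER_RANGE, size=n)
    trial_len = OFFER_DURATION + pre_jitter + CHOICE_DURATION + iti_jitter
    onsets = np.concatenate([[0.0], np.cumsum(trial_len)[:-1]])
    rows = [cells[i] for i in order]
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "domain": [r[0] for r in rows],
            "effort_level": [r[1] for r in rows],
            "reward": [r[2] for r in rows],
            "onset_s": onsets,
        }
    )


def simulate_choices(
    schedule: pd.DataFrame, truth: GroundTruth, seed: int = 0
) -> pd.DataFrame:
    """Simulate one subject's choices on a schedule from ground-truth parameters.

    Each trial's choice is a Bernoulli draw with p(offer) given by the softmax
    of the generating subjective value; an optional missing rate blanks
    responses to exercise exclusion logic.  Reaction times are drawn with a
    mild difficulty dependence (closer-to-indifference decisions are slower)
    purely for schema realism.
    """
    rng = np.random.default_rng(seed)
    p_offer = np.empty(len(schedule))
    for dom in DOMAINS:
        mask = (schedule["domain"] == dom).to_numpy()
        fam, k, beta = truth.domain_params(dom)
        sv = subjective_value(
            fam,
            schedule.loc[mask, "reward"].to_numpy(dtype=float),
            effort_code(schedule.loc[mask, "effort_level"].to_numpy()),
            k,
        )
        p_offer[mask] = choice_probability(sv, beta)
    chose_offer = rng.random(len(schedule)) < p_offer
    choice = np.where(chose_offer, "offer", "baseline")
    if truth.missing_rate > 0:
        choice = np.where(
            rng.random(len(schedule)) < truth.missing_rate, "missing", choice
        )
    rt = np.clip(
        rng.normal(0.6 + 1.4 * (0.5 - np.abs(p_offer - 0.5)), 0.15), 0.2, CHOICE_DURATION
    )
    rt = np.where(choice == "missing", np.nan, rt)
    out = schedule[["trial_index", "domain", "effort_level", "reward", "onset_s"]].copy()
    out.insert(0, "subject", truth.subject)
    out["choice"] = choice
    out["rt"] = rt
    return out


def simulate_training(truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate the training block: 10 trials per effort level 1-6 per domain.

    Each trial is rewarded with the ground truth's per-level success
    probability, so per-level reinforcement rates are recoverable summaries.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dom in DOMAINS:
        probs = truth.training_success[dom]
        for lev in TRAINING_EFFORT_LEVELS:
            p = probs[lev]
            rewarded = rng.random(TRAINING_TRIALS_PER_LEVEL) < p
            for i, r in enumerate(rewarded, start=1):
                rows.append((truth.subject, dom, lev, i, bool(r)))
    return pd.DataFrame(
        rows, columns=["subject", "domain", "effort_level", "trial_index", "rewarded"]
    )


def simulate_cohort(
    truths: list[GroundTruth], n_per_domain: int = 75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate choices and training for a cohort, one schedule draw each.

    Returns the concatenated long-format choice table and training table.
    Per-subject seeds are derived from ``seed`` so the cohort is reproducible
    and subjects are independent.
    """
    choices, training = [], []
    for i, truth in enumerate(truths):
        sched = generate_schedule(n_per_domain, seed=np.random.default_rng([seed, i, 0]).integers(2**31))
        choices.append(simulate_choices(sched, truth, seed=np.random.default_rng([seed, i, 1]).integers(2**31)))
        training.append(simulate_training(truth, seed=np.random.default_rng([seed, i, 2]).integers(2**31)))
    return pd.concat(choices, ignore_index=True), pd.concat(training, ignore_index=True)
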