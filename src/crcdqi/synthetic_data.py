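"""Synthetic respondent cohorts with known ground truth.

No respondent-level survey data are distributable, so every downstream
statistic is exercised against simulated cohorts whose generating
parameters are known exactly: per-item correctness probabilities (defaults
follow the published per-sample proportions), goal-importance
distributions with an explicit ceiling mass at 10, a logistic preference
structure linking goal ratings to the choice of colonoscopy vs another
test, a never-screened fraction, mode-specific missingness, and a retest
mechanism calibrated so each measure's population ICC equals its target.

Knowledge items are drawn independently given the arm (no within-
respondent correlation structure is imposed), and goal ratings are drawn
independently across goals; both are documented limitations.

Retest calibration uses a replay-or-redraw scheme: each retest value
repeats the test value with probability kappa and is otherwise a fresh
draw from the same marginal.  This leaves the marginal distribution
unchanged and makes the population test-retest correlation — hence the
ICC(2,1) — exactly kappa, for binary items and discrete ratings alike, so
target ICCs need no distribution-specific calibration.

One seed sequence per cohort is split into fixed, named substreams
(demographics, goals, screening, knowledge, involvement, missingness), so
e.g. toggling missingness never perturbs the earlier draws.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
import yaml

from .item_bank import ItemBank, default_item_bank
from .records import (
    Arm,
    DecisionMaker,
    Involvement,
    Mode,
    ResponseRecord,
    ScreeningHistory,
    Timepoint,
)

__all__ = [
    "GoalDistribution",
    "PreferenceTruth",
    "MissingRates",
    "CohortCell",
    "CohortSpec",
    "generate_cohort",
    "generate_retest",
    "preset",
    "PRESET_NAMES",
    "load_spec",
]

_STAGES = ("demographics", "goals", "screening", "knowledge", "involvement", "missingness", "retest")


class GoalDistribution(BaseModel):
    """Truncated, discretized normal importance distribution with an added
    point mass at the scale maximum (the observed ceiling behavior)."""

    model_config = ConfigDict(frozen=True)

    mean: float = 6.0
    sd: float = Field(2.5, gt=0)
    ceiling_mass: float = Field(0.0, ge=0.0, le=1.0)


class PreferenceTruth(BaseModel):
    """True logistic model P(colonoscopy | ratings) = s(intercept + b'x)."""

    model_config = ConfigDict(frozen=True)

    intercept: float
    coefficients: dict[str, float]


class MissingRates(BaseModel):
    model_config = ConfigDict(frozen=True)

    knowledge: float = Field(0.0, ge=0.0, le=1.0)
    goals: float = Field(0.0, ge=0.0, le=1.0)


class CohortCell(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(gt=0)
    arm: Arm = Arm.NONE
    mode: Mode = Mode.ONLINE


class CohortSpec(BaseModel):
    """Full generating specification for one cohort."""

    model_config = ConfigDict(frozen=True)

    cells: tuple[CohortCell, ...]
    id_prefix: str = "R"
    age_mean: float = 49.0
    age_sd: float = Field(9.0, gt=0)
    age_min: float = 35.0
    age_max: float = 70.0
    p_correct: dict[str, float]
    goal_dist: dict[str, GoalDistribution]
    preference_truth: PreferenceTruth
    never_screened_frac: float = Field(0.0, ge=0.0, le=1.0)
    #: probability the observed test contradicts the implied preference
    #: (threshold assignment only)
    decision_noise: float = Field(0.0, ge=0.0, le=1.0)
    #: "logistic": observed test ~ Bernoulli(true predicted probability);
    #: "threshold": observed test follows the implied preference, flipped
    #: with probability decision_noise
    assignment: str = "logistic"
    missing_rates: dict[str, MissingRates] = Field(default_factory=dict)
    retest_icc_knowledge: float = Field(0.67, ge=0.0, le=1.0)
    retest_icc_goals: dict[str, float] = Field(default_factory=dict)
    p_decision_maker: dict[str, float] = Field(
        default_factory=lambda: {"patient": 0.30, "doctor": 0.37, "shared": 0.33}
    )
    seed: int = 0

    @field_validator("p_correct")
    @classmethod
    def _probs(cls, v):
        for item, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_correct[{item}] = {p} outside [0, 1]")
        return v

    @field_validator("assignment")
    @classmethod
    def _assignment(cls, v):
        if v not in ("logistic", "threshold"):
            raise ValueError(f"assignment must be 'logistic' or 'threshold', got {v!r}")
        return v

    @field_validator("retest_icc_goals")
    @classmethod
    def _iccs(cls, v):
        for g, icc in v.items():
            if not (0.0 <= icc <= 1.0):
                raise ValueError(f"retest_icc_goals[{g}] = {icc} outside [0, 1]")
        return v

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cells)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_spec(source) -> CohortSpec:
    """Load a cohort spec from a YAML path or mapping."""
    if not isinstance(source, dict):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    return CohortSpec(**source)


def _streams(seed: int, label: int = 0) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(entropy=seed, spawn_key=(label,)).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _draw_rating(rng: np.random.Generator, dist: GoalDistribution) -> int:
    if rng.random() < dist.ceiling_mass:
        return 10
    x = rng.normal(dist.mean, dist.sd)
    return int(np.clip(round(x), 0, 10))


def _draw_response(
    rng: np.random.Generator, p_correct: float, options: Sequence[str], correct: str
) -> str:
    if rng.random() < p_correct:
        return correct
    wrong = [o for o in options if o != correct]
    return wrong[rng.integers(len(wrong))]


def generate_cohort(
    spec: CohortSpec, bank: Optional[ItemBank] = None
) -> list[ResponseRecord]:
    """Generate one cohort; byte-identical under a fixed spec.

    Screening history is drawn from the true preference model applied to
    the respondent's goal ratings (see ``assignment``); never-screened
    status is assigned first, independently of the ratings.  Knowledge
    responses are independent across items at the spec probabilities;
    missingness (completely at random, per mode) is applied last.
    """
    bank = bank if bank is not None else default_item_bank()
    for item_id in spec.p_correct:
        if item_id not in bank.item_ids:
            raise ValueError(f"p_correct references unknown item {item_id!r}")
    for goal_id in spec.goal_dist:
        if goal_id not in bank.goal_ids:
            raise ValueError(f"goal_dist references unknown goal {goal_id!r}")
    for goal_id in spec.preference_truth.coefficients:
        if goal_id not in bank.goal_ids:
            raise ValueError(f"preference_truth references unknown goal {goal_id!r}")

    rng = _streams(spec.seed)
    records: list[ResponseRecord] = []
    idx = 0
    dm_labels = list(spec.p_decision_maker)
    dm_probs = np.array([spec.p_decision_maker[k] for k in dm_labels], dtype=float)
    dm_probs = dm_probs / dm_probs.sum()

    for cell in spec.cells:
        for _ in range(cell.n):
            idx += 1
            rid = f"{spec.id_prefix}{idx:05d}"
            age = float(
                np.clip(
                    rng["demographics"].normal(spec.age_mean, spec.age_sd),
                    spec.age_min,
                    spec.age_max,
                )
            )
            sex = "female" if rng["demographics"].random() < 0.6 else "male"

            ratings: dict[str, Optional[int]] = {}
            for goal in bank.goal_items:
                dist = spec.goal_dist.get(goal.goal_id, GoalDistribution())
                ratings[goal.goal_id] = _draw_rating(rng["goals"], dist)

            eta = spec.preference_truth.intercept
            for g, b in spec.preference_truth.coefficients.items():
                eta += b * float(ratings[g])  # type: ignore[arg-type]
            p_col = 1.0 / (1.0 + math.exp(-eta))
            if rng["screening"].random() < spec.never_screened_frac:
                history = ScreeningHistory.NEVER
            elif spec.assignment == "logistic":
                history = (
                    ScreeningHistory.COLONOSCOPY
                    if rng["screening"].random() < p_col
                    else ScreeningHistory.OTHER_TEST
                )
            else:
                implied = p_col > 0.5
                if rng["screening"].random() < spec.decision_noise:
                    implied = not implied
                history = (
                    ScreeningHistory.COLONOSCOPY if implied else ScreeningHistory.OTHER_TEST
                )

            responses: dict[str, Optional[str]] = {}
            for item in bank.knowledge_items:
                p = spec.p_correct.get(item.item_id, 0.5)
                responses[item.item_id] = _draw_response(
                    rng["knowledge"], p, item.options, item.correct_option
                )

            weights = np.array(
                [float(ratings[g]) + 0.5 for g in bank.goal_ids], dtype=float
            )
            weights = weights / weights.sum()
            top3 = frozenset(
                rng["involvement"].choice(
                    bank.goal_ids, size=min(3, len(bank.goal_ids)), replace=False, p=weights
                )
            )
            dm = DecisionMaker(dm_labels[rng["involvement"].choice(len(dm_labels), p=dm_probs)])
            level = int(rng["involvement"].integers(1, 6))

            rates = spec.missing_rates.get(cell.mode.value, MissingRates())
            for item_id in list(responses):
                if rng["missingness"].random() < rates.knowledge:
                    responses[item_id] = None
            for goal_id in list(ratings):
                if rng["missingness"].random() < rates.goals:
                    ratings[goal_id] = None

            records.append(
                ResponseRecord(
                    respondent_id=rid,
                    timepoint=Timepoint.TEST,
                    arm=cell.arm,
                    mode=cell.mode,
                    age=age,
                    sex=sex,
                    screening_history=history,
                    knowledge_responses=responses,
                    goal_ratings=ratings,
                    top_three=top3,
                    involvement=Involvement(decision_maker=dm, involvement_level=level),
                )
            )
    return records


def generate_retest(
    cohort: Sequence[ResponseRecord],
    spec: CohortSpec,
    bank: Optional[ItemBank] = None,
) -> list[ResponseRecord]:
    """Retest records for a cohort generated from the same spec.

    Each knowledge response is replayed with probability
    ``retest_icc_knowledge`` and otherwise redrawn at the item's spec
    probability; each goal rating is replayed with its goal's target ICC
    and otherwise redrawn from its marginal.  Missingness is re-applied
    independently at the mode rates.
    """
    bank = bank if bank is not None else default_item_bank()
    rng = _streams(spec.seed, label=1)

    retest: list[ResponseRecord] = []
    for rec in cohort:
        responses: dict[str, Optional[str]] = {}
        for item in bank.knowledge_items:
            prev = rec.knowledge_responses.get(item.item_id)
            if prev is not None and rng["retest"].random() < spec.retest_icc_knowledge:
                responses[item.item_id] = prev
            else:
                p = spec.p_correct.get(item.item_id, 0.5)
                responses[item.item_id] = _draw_response(
                    rng["retest"], p, item.options, item.correct_option
                )
        ratings: dict[str, Optional[int]] = {}
        for goal in bank.goal_items:
            prev_r = rec.goal_ratings.get(goal.goal_id)
            kappa = spec.retest_icc_goals.get(goal.goal_id, spec.retest_icc_knowledge)
            if prev_r is not None and rng["retest"].random() < kappa:
                ratings[goal.goal_id] = prev_r
            else:
                dist = spec.goal_dist.get(goal.goal_id, GoalDistribution())
                ratings[goal.goal_id] = _draw_rating(rng["retest"], dist)

        rates = spec.missing_rates.get(rec.mode.value, MissingRates())
        for item_id in list(responses):
            if rng["missingness"].random() < rates.knowledge:
                responses[item_id] = None
        for goal_id in list(ratings):
            if rng["missingness"].random() < rates.goals:
                ratings[goal_id] = None

        retest.append(
            ResponseRecord(
                respondent_id=rec.respondent_id,
                timepoint=Timepoint.RETEST,
                arm=rec.arm,
                mode=rec.mode,
                age=rec.age,
                sex=rec.sex,
                education=rec.education,
                race=rec.race,
                screening_history=rec.screening_history,
                knowledge_responses=responses,
                goal_ratings=ratings,
                top_three=rec.top_three,
                involvement=rec.involvement,
            )
        )
    return retest


# --------------------------------------------------------------------------
# Presets parameterized from the published per-sample summaries.

#: Per-item proportion correct by sample (counts over sample size).
_P_CORRECT = {
    "online_da": {  # N = 163
        "K01": 150 / 163, "K02": 109 / 163, "K03": 155 / 163, "K04": 151 / 163,
        "K05": 140 / 163, "K06": 147 / 163, "K07": 156 / 163, "K08": 92 / 163,
        "K09": 136 / 163, "K10": 133 / 163,
    },
    "online_control": {  # N = 175
        "K01": 126 / 175, "K02": 63 / 175, "K03": 168 / 175, "K04": 125 / 175,
        "K05": 96 / 175, "K06": 115 / 175, "K07": 160 / 175, "K08": 72 / 175,
        "K09": 148 / 175, "K10": 53 / 175,
    },
    "provider": {  # N = 115
        "K01": 114 / 115, "K02": 66 / 115, "K03": 113 / 115, "K04": 109 / 115,
        "K05": 112 / 115, "K06": 111 / 115, "K07": 113 / 115, "K08": 100 / 115,
        "K09": 110 / 115, "K10": 73 / 115,
    },
    "clinic": {  # N = 94
        "K01": 50 / 94, "K02": 6 / 94, "K03": 81 / 94, "K04": 55 / 94,
        "K05": 28 / 94, "K06": 48 / 94, "K07": 70 / 94, "K08": 21 / 94,
        "K09": 71 / 94, "K10": 12 / 94,
    },
}

#: Goal importance distributions.  Ceiling masses for G_KNOW / G_EARLY /
#: G_HARM are calibrated so the total share of 10/10 ratings is about
#: 64% / 57% / 56%, the observed top-of-scale shares.
_GOAL_DIST = {
    "G_KNOW": GoalDistribution(mean=8.0, sd=2.0, ceiling_mass=0.53),
    "G_EARLY": GoalDistribution(mean=8.0, sd=2.0, ceiling_mass=0.44),
    "G_HARM": GoalDistribution(mean=7.5, sd=2.5, ceiling_mass=0.44),
    "G_TUBE": GoalDistribution(mean=6.0, sd=3.0, ceiling_mass=0.0),
    "G_PAIN": GoalDistribution(mean=6.5, sd=2.5, ceiling_mass=0.05),
    "G_COST": GoalDistribution(mean=5.5, sd=3.0, ceiling_mass=0.05),
    "G_YEARLY": GoalDistribution(mean=5.5, sd=3.0, ceiling_mass=0.05),
    "G_SLEEPY": GoalDistribution(mean=5.0, sd=3.0, ceiling_mass=0.0),
}

#: True preference coefficients on the published odds-ratio scale
#: (log odds of colonoscopy per importance point); the intercept places
#: the colonoscopy share among the screened near 70%.
_TRUTH = PreferenceTruth(
    intercept=0.25,
    coefficients={
        "G_KNOW": math.log(1.83),
        "G_TUBE": math.log(0.70),
        "G_HARM": math.log(0.84),
        "G_EARLY": math.log(0.74),
        "G_YEARLY": math.log(1.15),
        "G_COST": math.log(0.95),
        "G_PAIN": math.log(1.19),
    },
)

#: Mode-specific missing-data rates (per item): online administrations
#: nearly complete, paper forms a few percent, in-person in between.
_MISSING = {
    "online": MissingRates(knowledge=0.002, goals=0.005),
    "mail": MissingRates(knowledge=0.025, goals=0.009),
    "in_person": MissingRates(knowledge=0.032, goals=0.040),
}

#: Per-goal target retest ICCs.
_RETEST_GOALS = {
    "G_EARLY": 0.87, "G_KNOW": 0.85, "G_TUBE": 0.74, "G_PAIN": 0.68,
    "G_HARM": 0.68, "G_COST": 0.61, "G_YEARLY": 0.47, "G_SLEEPY": 0.55,
}

PRESET_NAMES = ("online_da", "online_control", "clinic", "provider")


def preset(name: str, seed: int = 0) -> CohortSpec:
    """A shipped cohort spec emulating one of the study samples.

    ``online_da`` / ``online_control``: the two randomized arms of the
    online study (surveys split between online and mail administration);
    ``clinic``: the community-health-center sample, interviewed in person,
    ages 50+; ``provider``: the mailed physician survey.
    """
    if name == "online_da":
        return CohortSpec(
            cells=(
                CohortCell(n=82, arm=Arm.DECISION_AID, mode=Mode.ONLINE),
                CohortCell(n=81, arm=Arm.DECISION_AID, mode=Mode.MAIL),
            ),
            id_prefix="DA",
            age_mean=49.0, age_sd=9.1, age_min=35.0, age_max=70.0,
            p_correct=_P_CORRECT["online_da"],
            goal_dist=_GOAL_DIST,
            preference_truth=_TRUTH,
            never_screened_frac=34 / 80,
            missing_rates=_MISSING,
            retest_icc_knowledge=0.67,
            retest_icc_goals=_RETEST_GOALS,
            seed=seed,
        )
    if name == "online_control":
        return CohortSpec(
            cells=(
                CohortCell(n=88, arm=Arm.CONTROL, mode=Mode.ONLINE),
                CohortCell(n=87, arm=Arm.CONTROL, mode=Mode.MAIL),
            ),
            id_prefix="CT",
            age_mean=48.5, age_sd=9.2, age_min=35.0, age_max=70.0,
            p_correct=_P_CORRECT["online_control"],
            goal_dist=_GOAL_DIST,
            preference_truth=_TRUTH,
            never_screened_frac=19 / 68,
            missing_rates=_MISSING,
            retest_icc_knowledge=0.67,
            retest_icc_goals=_RETEST_GOALS,
            seed=seed,
        )
    if name == "clinic":
        return CohortSpec(
            cells=(CohortCell(n=94, arm=Arm.NONE, mode=Mode.IN_PERSON),),
            id_prefix="CL",
            age_mean=59.6, age_sd=8.3, age_min=50.0, age_max=90.0,
            p_correct=_P_CORRECT["clinic"],
            goal_dist=_GOAL_DIST,
            preference_truth=_TRUTH,
            never_screened_frac=29 / 94,
            missing_rates=_MISSING,
            retest_icc_knowledge=0.67,
            retest_icc_goals=_RETEST_GOALS,
            seed=seed,
        )
    if name == "provider":
        return CohortSpec(
            cells=(CohortCell(n=115, arm=Arm.NONE, mode=Mode.MAIL),),
            id_prefix="PR",
            age_mean=53.0, age_sd=9.0, age_min=30.0, age_max=80.0,
            p_correct=_P_CORRECT["provider"],
            goal_dist=_GOAL_DIST,
            preference_truth=_TRUTH,
            never_screened_frac=0.0,
            missing_rates=_MISSING,
            retest_icc_knowledge=0.67,
            retest_icc_goals=_RETEST_GOALS,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
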