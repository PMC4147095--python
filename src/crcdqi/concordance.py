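"""Goal-concordance scoring via a fitted preference model.

The instrument infers each respondent's test preference from their goal
importance ratings.  A logistic regression of screening group (colonoscopy
vs. some other test) on the 0-10 goal ratings is fit over respondents aged
50+ who have been screened; the fitted model then assigns every eligible
respondent a predicted probability of colonoscopy.  A respondent "matches"
when that probability exceeds 0.5 and they had a colonoscopy, or is at or
below 0.5 and they had some other test.  Never-screened respondents are
kept out of the fit and are never counted as matching, but still receive a
predicted probability and an implied preference.  The cohort concordance
score is the percentage of eligible respondents who match.

Ratings enter the model raw (no standardization), so each exponentiated
coefficient is the odds ratio of colonoscopy per one-point increase in
importance of that goal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .item_bank import ItemBank
from .records import ResponseRecord, ScreeningHistory

__all__ = [
    "ELIGIBLE_AGE",
    "FitError",
    "SeparationError",
    "FitDiagnostics",
    "PreferenceModel",
    "MatchResult",
    "ConcordanceResult",
    "fit_preference_model",
    "classify_match",
    "concordance_score",
    "never_screened_preference_summary",
]

logger = logging.getLogger(__name__)

#: Minimum age of the analytic population for concordance (screening
#: guidelines address adults 50+; younger respondents are enrolled only to
#: spread the knowledge-score distribution).
ELIGIBLE_AGE = 50.0

_SCREENED = (ScreeningHistory.COLONOSCOPY, ScreeningHistory.OTHER_TEST)


class FitError(ValueError):
    """The preference model cannot be fit on the given cohort."""


class SeparationError(FitError):
    """Complete or quasi-complete separation: the unpenalized maximum
    likelihood estimate does not exist.  Refit with fewer covariates or an
    explicitly penalized model; penalization is never applied silently."""


@dataclass(frozen=True)
class FitDiagnostics:
    n_fit: int
    n_colonoscopy: int
    n_other: int
    converged: bool
    separation_detected: bool


@dataclass(frozen=True)
class PreferenceModel:
    """A fitted (or externally specified) goal -> test-choice model.

    ``coefficients`` are log-odds of colonoscopy per rating point, keyed
    exactly by ``covariate_goals``.  ``coef_se`` holds Wald standard errors
    when the model was fit from data.  ``imputation_medians`` are the
    fit-subset median ratings used to impute a single missing rating at
    classification time.
    """

    covariate_goals: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    fit_diagnostics: Optional[FitDiagnostics] = None
    coef_se: dict[str, float] = field(default_factory=dict)
    intercept_se: Optional[float] = None
    imputation_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.covariate_goals):
            raise ValueError("coefficients must be keyed exactly by covariate_goals")

    def odds_ratios(self) -> dict[str, float]:
        return {g: math.exp(b) for g, b in self.coefficients.items()}

    def wald_ci(self, goal_id: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one odds ratio."""
        from scipy.stats import norm

        if goal_id not in self.coef_se:
            raise KeyError(f"no standard error stored for {goal_id!r}")
        z = norm.ppf(0.5 + level / 2)
        b, se = self.coefficients[goal_id], self.coef_se[goal_id]
        return math.exp(b - z * se), math.exp(b + z * se)

    def linear_predictor(self, ratings: dict[str, float]) -> float:
        eta = self.intercept
        for g in self.covariate_goals:
            eta += self.coefficients[g] * ratings[g]
        return eta

    def predicted_probability(self, ratings: dict[str, float]) -> float:
        """P(colonoscopy) = logistic(intercept + sum(beta_g * rating_g))."""
        return 1.0 / (1.0 + math.exp(-self.linear_predictor(ratings)))


@dataclass(frozen=True)
class MatchResult:
    """Classification of one eligible respondent's decision.

    ``match`` is True iff (predicted_prob > 0.5 and observed colonoscopy)
    or (predicted_prob <= 0.5 and observed other test).  The tie at exactly
    0.5 therefore implies an other-test preference.  Never-screened
    respondents have ``match`` False by definition.
    """

    respondent_id: str
    eligible: bool
    predicted_prob: Optional[float]
    implied_preference: Optional[ScreeningHistory]
    observed: Optional[ScreeningHistory]
    match: bool

    def __post_init__(self) -> None:
        if self.predicted_prob is not None:
            implied = (
                ScreeningHistory.COLONOSCOPY
                if self.predicted_prob > 0.5
                else ScreeningHistory.OTHER_TEST
            )
            if self.implied_preference != implied:
                raise ValueError(
                    f"{self.respondent_id}: implied_preference inconsistent with "
                    f"predicted_prob={self.predicted_prob}"
                )


@dataclass(frozen=True)
class ConcordanceResult:
    model: PreferenceModel
    matches: tuple[MatchResult, ...]
    n_eligible: int
    n_match: int
    concordance_pct: float
    n_excluded: int = 0  # age-eligible respondents without a classifiable record


def _fit_rows(
    cohort: Sequence[ResponseRecord], goals: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and outcome for the fit subset: age 50+, screened,
    complete ratings on every model goal."""
    X_rows, y = [], []
    for rec in cohort:
        if rec.age is None or rec.age < ELIGIBLE_AGE:
            continue
        if rec.screening_history not in _SCREENED:
            continue
        ratings = [rec.goal_ratings.get(g) for g in goals]
        if any(r is None for r in ratings):
            continue
        X_rows.append([float(r) for r in ratings])  # type: ignore[arg-type]
        y.append(1.0 if rec.screening_history is ScreeningHistory.COLONOSCOPY else 0.0)
    return np.asarray(X_rows, dtype=float), np.asarray(y, dtype=float)


def fit_preference_model(
    cohort: Sequence[ResponseRecord],
    bank: ItemBank,
    goals: Optional[Sequence[str]] = None,
) -> PreferenceModel:
    """Maximum-likelihood logistic fit of colonoscopy (1) vs other test (0)
    on the goal importance ratings.

    Only respondents aged 50+ with a screening test and complete ratings on
    every model goal enter the fit; never-screened respondents are always
    excluded.  Raises :class:`FitError` when an outcome class is absent and
    :class:`SeparationError` on complete separation.
    """
    goal_list = tuple(goals if goals is not None else bank.model_goals)
    X, y = _fit_rows(cohort, goal_list)
    n_col = int(y.sum()) if y.size else 0
    n_oth = int(y.size - n_col)
    if n_col == 0 or n_oth == 0:
        raise FitError(
            "preference-model fit needs both outcome classes; got "
            f"{n_col} colonoscopy and {n_oth} other-test respondents"
        )

    # constant covariates carry no information and would make the design
    # singular; they get coefficient 0 and stay out of the optimization
    variances = X.var(axis=0)
    active = [j for j in range(X.shape[1]) if variances[j] > 0]
    exog = sm.add_constant(X[:, active], has_constant="add")
    if not active:
        base = float(y.mean())
        if base <= 0.0 or base >= 1.0:
            raise FitError("degenerate outcome after dropping constant covariates")
        medians = {g: float(np.median(X[:, j])) for j, g in enumerate(goal_list)}
        return PreferenceModel(
            covariate_goals=goal_list,
            intercept=math.log(base / (1 - base)),
            coefficients={g: 0.0 for g in goal_list},
            fit_diagnostics=FitDiagnostics(
                n_fit=int(y.size),
                n_colonoscopy=n_col,
                n_other=n_oth,
                converged=True,
                separation_detected=False,
            ),
            imputation_medians=medians,
        )
    try:
        with warnings.catch_warnings():
            # transient overflow inside Newton steps is harmless; only the
            # explicit separation signal is escalated
            warnings.simplefilter("ignore", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, exog).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            "complete separation detected while fitting the preference model; "
            "refit with fewer covariates or an explicitly penalized model"
        ) from exc

    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.linalg.norm(params[1:]) > 50:
        raise SeparationError(
            "diverging coefficients indicate separation; the unpenalized "
            "maximum-likelihood estimate does not exist for this cohort"
        )

    bse = np.asarray(res.bse, dtype=float)
    medians = {
        g: float(np.median(X[:, j])) for j, g in enumerate(goal_list)
    }
    col_of = {j: pos for pos, j in enumerate(active)}
    coefficients = {
        g: (float(params[1 + col_of[j]]) if j in col_of else 0.0)
        for j, g in enumerate(goal_list)
    }
    coef_se = {
        g: float(bse[1 + col_of[j]]) for j, g in enumerate(goal_list) if j in col_of
    }
    return PreferenceModel(
        covariate_goals=goal_list,
        intercept=float(params[0]),
        coefficients=coefficients,
        fit_diagnostics=FitDiagnostics(
            n_fit=int(y.size),
            n_colonoscopy=n_col,
            n_other=n_oth,
            converged=bool(res.mle_retvals.get("converged", True)),
            separation_detected=False,
        ),
        coef_se=coef_se,
        intercept_se=float(bse[0]),
        imputation_medians=medians,
    )


def classify_match(model: PreferenceModel, record: ResponseRecord) -> MatchResult:
    """Classify one respondent aged 50+ as matching their goals or not.

    A single missing model-goal rating is imputed with the fit-subset
    median; with more than one missing (or no medians available) the
    predicted probability is undefined and the respondent is flagged for
    exclusion from the eligible denominator.
    """
    if record.age is None or record.age < ELIGIBLE_AGE:
        raise ValueError(
            f"{record.respondent_id}: concordance applies to respondents aged "
            f"{ELIGIBLE_AGE:.0f}+ (age={record.age})"
        )
    ratings: dict[str, float] = {}
    n_missing = 0
    for g in model.covariate_goals:
        r = record.goal_ratings.get(g)
        if r is None:
            n_missing += 1
            if n_missing <= 1 and g in model.imputation_medians:
                ratings[g] = model.imputation_medians[g]
        else:
            ratings[g] = float(r)

    observed = record.screening_history
    if len(ratings) < len(model.covariate_goals):
        logger.warning(
            "%s: %d missing model-goal rating(s); predicted probability "
            "undefined, respondent excluded from the concordance denominator",
            record.respondent_id,
            n_missing,
        )
        return MatchResult(
            respondent_id=record.respondent_id,
            eligible=False,
            predicted_prob=None,
            implied_preference=None,
            observed=observed,
            match=False,
        )

    prob = model.predicted_probability(ratings)
    implied = (
        ScreeningHistory.COLONOSCOPY if prob > 0.5 else ScreeningHistory.OTHER_TEST
    )
    match = observed in _SCREENED and observed == implied
    return MatchResult(
        respondent_id=record.respondent_id,
        eligible=True,
        predicted_prob=prob,
        implied_preference=implied,
        observed=observed,
        match=match,
    )


def concordance_score(
    cohort: Sequence[ResponseRecord],
    bank: ItemBank,
    model: Optional[PreferenceModel] = None,
) -> ConcordanceResult:
    """Fit (unless a model is supplied) and summarize concordance.

    ``n_eligible`` counts every respondent aged 50+ with a defined match
    classification — including the never-screened, who can only count
    against concordance.  The percentage and both counts are reported so
    the denominator is never ambiguous.
    """
    if model is None:
        model = fit_preference_model(cohort, bank)
    matches = []
    n_excluded = 0
    for rec in cohort:
        if rec.age is None or rec.age < ELIGIBLE_AGE:
            continue
        result = classify_match(model, rec)
        if result.eligible and result.observed is None:
            # unknown screening history: classifiable preference but no
            # observable decision to compare against
            n_excluded += 1
            continue
        if not result.eligible:
            n_excluded += 1
            continue
        matches.append(result)
    n_eligible = len(matches)
    if n_eligible == 0:
        raise FitError("no eligible respondents with a defined match classification")
    n_match = sum(1 for m in matches if m.match)
    return ConcordanceResult(
        model=model,
        matches=tuple(matches),
        n_eligible=n_eligible,
        n_match=n_match,
        concordance_pct=100.0 * n_match / n_eligible,
        n_excluded=n_excluded,
    )


def never_screened_preference_summary(
    result: ConcordanceResult,
) -> tuple[float, float]:
    """Among eligible never-screened respondents, the percentages whose
    goals imply a colonoscopy vs an other-test preference (sums to 100)."""
    never = [
        m for m in result.matches if m.observed is ScreeningHistory.NEVER
    ]
    if not never:
        raise ValueError("no never-screened respondents among the eligible")
    n_col = sum(
        1 for m in never if m.implied_preference is ScreeningHistory.COLONOSCOPY
    )
    pct_col = 100.0 * n_col / len(never)
    return pct_col, 100.0 - pct_col
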