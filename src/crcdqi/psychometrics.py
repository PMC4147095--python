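"""Psychometric evaluation protocol for the instrument.

Covers test-retest reliability (intraclass correlation), discriminant
validity (two-sample knowledge contrasts), construct validity (association
of decision quality with self-reported involvement), feasibility (missing
data and response rates, by administration mode), item-retention
diagnostics (difficulty, ceiling, redundancy, top-three endorsement), and
reproducibility of the five-item brief knowledge form.

The ICC is the two-way random-effects, absolute-agreement, single-
measurement form — ICC(A,1) in McGraw & Wong's taxonomy, ICC(2,1) in
Shrout & Fleiss's — the standard choice for test-retest agreement of a
single administration, with the F-distribution 95% confidence bounds.
The conventional adequacy target is 0.7.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .item_bank import ItemBank
from .records import Mode, ResponseRecord
from .scoring import KnowledgeResult, score_brief, score_knowledge

__all__ = [
    "ICC_TARGET",
    "ICCResult",
    "GroupContrast",
    "RetentionThresholds",
    "ItemDiagnostics",
    "RetentionFlag",
    "FeasibilityReport",
    "BriefReproducibility",
    "retest_reliability",
    "knowledge_contrast",
    "involvement_association",
    "feasibility_report",
    "item_retention_screen",
    "brief_reproducibility",
]

logger = logging.getLogger(__name__)

#: Conventional adequacy target for test-retest reliability.
ICC_TARGET = 0.7


@dataclass(frozen=True)
class ICCResult:
    measure_id: str
    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int
    model_form: str = "two-way random, absolute agreement, single measurement (ICC 2,1)"
    target: float = ICC_TARGET

    @property
    def meets_target(self) -> bool:
        return self.icc >= self.target


def retest_reliability(
    pairs: Sequence[tuple[float, float]], measure_id: str
) -> ICCResult:
    """ICC(2,1) over (test, retest) value pairs with an F-based 95% CI.

    Pairs with a missing member must be dropped by the caller; at least 3
    complete pairs are required.  Zero between-subject variance makes
    agreement unidentifiable and is reported as ICC 0 with a warning.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (test, retest) tuples")
    if np.isnan(data).any():
        raise ValueError("pairs must be complete; drop incomplete pairs first")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 complete pairs, got {n}")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    occ_means = data.mean(axis=0)
    # two-way ANOVA mean squares: rows = subjects, columns = occasions
    ms_r = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((occ_means - grand) ** 2) / (k - 1)
    resid = data - subj_means[:, None] - occ_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))

    if ms_r <= 1e-300:
        logger.warning(
            "%s: zero between-subject variance; ICC undefined, reporting 0",
            measure_id,
        )
        return ICCResult(measure_id=measure_id, icc=0.0, ci_low=0.0, ci_high=0.0, n_pairs=n)

    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    icc = (ms_r - ms_e) / denom

    # McGraw & Wong F-based bounds for ICC(A,1)
    alpha = 0.05
    if ms_e <= 0 and ms_c <= ms_e:
        lo = hi = icc  # perfect agreement: degenerate interval
    else:
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = icc
        else:
            v = (a * ms_c + b * ms_e) ** 2 / (
                (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (ms_r - f_l * ms_e)
                / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
            )
            hi = (
                n * (f_u * ms_r - ms_e)
                / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r)
            )
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(
        measure_id=measure_id, icc=float(icc), ci_low=float(lo), ci_high=float(hi), n_pairs=n
    )


@dataclass(frozen=True)
class GroupContrast:
    contrast_id: str
    mean_a: float
    mean_b: float
    estimate: float  # difference a - b (means or proportions)
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(f"{self.contrast_id}: CI does not contain the estimate")


ScoreLike = Union[float, KnowledgeResult]


def _scores(values: Sequence[ScoreLike]) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, KnowledgeResult):
            if v.defined:
                out.append(v.score_pct)
        else:
            out.append(float(v))
    return np.asarray(out, dtype=float)


def knowledge_contrast(
    cohort_a: Sequence[ScoreLike],
    cohort_b: Sequence[ScoreLike],
    contrast_id: str = "knowledge",
) -> GroupContrast:
    """Welch two-sample t-test on knowledge scores, with the difference in
    means (a - b) and its 95% confidence interval."""
    a, b = _scores(cohort_a), _scores(cohort_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 defined scores")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constant cohorts: no evidence of a difference
            return GroupContrast(
                contrast_id=contrast_id,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                estimate=0.0,
                ci_low=0.0,
                ci_high=0.0,
                p_value=1.0,
                test="welch-t",
                n_a=len(a),
                n_b=len(b),
            )
        raise ValueError("both cohorts are constant; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return GroupContrast(
        contrast_id=contrast_id,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        estimate=float(a.mean() - b.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        test="welch-t",
        n_a=len(a),
        n_b=len(b),
    )


def involvement_association(
    high_quality_flags: Sequence[bool],
    doctor_made_flags: Sequence[bool],
    contrast_id: str = "dqi-by-involvement",
) -> GroupContrast:
    """Fisher's exact test of high decision quality against doctor-made
    decisions.

    Reports the proportion reporting a doctor-made decision within the
    high-quality and the not-high-quality groups, the difference with a
    Wald 95% CI, and the exact two-sided p-value.
    """
    hq = np.asarray(high_quality_flags, dtype=bool)
    doc = np.asarray(doctor_made_flags, dtype=bool)
    if hq.shape != doc.shape:
        raise ValueError("flag sequences must be the same length")
    n1, n0 = int(hq.sum()), int((~hq).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both high-quality and not-high-quality respondents")
    a = int((hq & doc).sum())  # high quality, doctor-made
    c = int((~hq & doc).sum())
    table = np.array([[a, n1 - a], [c, n0 - c]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    p1, p0 = a / n1, c / n0
    diff = p1 - p0
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    z = stats.norm.ppf(0.975)
    return GroupContrast(
        contrast_id=contrast_id,
        mean_a=100.0 * p1,
        mean_b=100.0 * p0,
        estimate=100.0 * diff,
        ci_low=100.0 * (diff - z * se),
        ci_high=100.0 * (diff + z * se),
        p_value=float(p),
        test="fisher-exact",
        n_a=n1,
        n_b=n0,
    )


@dataclass(frozen=True)
class FeasibilityReport:
    n_respondents: int
    knowledge_missing_pct: float  # mean per-respondent % of knowledge items missing
    goals_missing_pct: float
    knowledge_missing_by_mode: dict[str, float]
    goals_missing_by_mode: dict[str, float]
    mode_contrast_knowledge: Optional[GroupContrast]
    mode_contrast_goals: Optional[GroupContrast]
    response_rate_pct: Optional[float]
    n_invited: Optional[int]


def feasibility_report(
    cohort: Sequence[ResponseRecord],
    bank: ItemBank,
    invited: Optional[int] = None,
) -> FeasibilityReport:
    """Missing-data rates per scale, overall and by administration mode.

    When two or more modes are present, the two largest mode groups are
    compared with a Welch t-test on respondent-level missing fractions.
    The response rate is reported when the invited count is supplied.
    """
    if not cohort:
        raise ValueError("feasibility_report requires a nonempty cohort")
    item_ids = bank.item_ids
    goal_ids = bank.goal_ids

    def missing_fracs(rec: ResponseRecord) -> tuple[float, float]:
        k_missing = sum(1 for i in item_ids if rec.knowledge_responses.get(i) is None)
        g_missing = sum(1 for g in goal_ids if rec.goal_ratings.get(g) is None)
        return 100.0 * k_missing / len(item_ids), 100.0 * g_missing / len(goal_ids)

    by_mode: dict[str, list[tuple[float, float]]] = {}
    all_fracs = []
    for rec in cohort:
        fr = missing_fracs(rec)
        all_fracs.append(fr)
        by_mode.setdefault(rec.mode.value, []).append(fr)

    k_all = float(np.mean([f[0] for f in all_fracs]))
    g_all = float(np.mean([f[1] for f in all_fracs]))
    k_by_mode = {m: float(np.mean([f[0] for f in v])) for m, v in by_mode.items()}
    g_by_mode = {m: float(np.mean([f[1] for f in v])) for m, v in by_mode.items()}

    contrast_k = contrast_g = None
    if len(by_mode) >= 2:
        m1, m2 = sorted(by_mode, key=lambda m: (-len(by_mode[m]), m))[:2]
        try:
            contrast_k = knowledge_contrast(
                [f[0] for f in by_mode[m1]],
                [f[0] for f in by_mode[m2]],
                contrast_id=f"knowledge-missing:{m1}-vs-{m2}",
            )
            contrast_g = knowledge_contrast(
                [f[1] for f in by_mode[m1]],
                [f[1] for f in by_mode[m2]],
                contrast_id=f"goals-missing:{m1}-vs-{m2}",
            )
        except ValueError:
            logger.warning("mode comparison degenerate; skipping contrast")

    response_rate = 100.0 * len(cohort) / invited if invited else None
    return FeasibilityReport(
        n_respondents=len(cohort),
        knowledge_missing_pct=k_all,
        goals_missing_pct=g_all,
        knowledge_missing_by_mode=k_by_mode,
        goals_missing_by_mode=g_by_mode,
        mode_contrast_knowledge=contrast_k,
        mode_contrast_goals=contrast_g,
        response_rate_pct=response_rate,
        n_invited=invited,
    )


class RetentionFlag(str, enum.Enum):
    RETAIN = "retain"
    REVISE = "revise"
    DROP = "drop"


@dataclass(frozen=True)
class RetentionThresholds:
    """Deterministic screening thresholds; flags are a pure function of
    (data, thresholds).

    too_easy: difficulty above which a knowledge item is flagged (>0.85).
    ceiling_share: share of top-of-scale ratings above which a goal is
    flagged for ceiling.  top_three_min: minimum share of respondents
    naming a goal among their top three for it to survive a ceiling flag.
    redundancy_r: absolute inter-item correlation above which a pair is
    flagged redundant.
    """

    too_easy: float = 0.85
    ceiling_share: float = 0.50
    top_three_min: float = 0.10
    redundancy_r: float = 0.80
    min_cohort: int = 30


@dataclass(frozen=True)
class ItemDiagnostics:
    item_id: str
    kind: str  # "knowledge" | "goal"
    metric: float  # difficulty (knowledge) or top-of-scale share (goal)
    redundancy_r: float
    redundancy_partner: Optional[str]
    top_three_pct: Optional[float]  # goals only
    flag: RetentionFlag
    reasons: tuple[str, ...]


def _pairwise_max_corr(matrix: np.ndarray, ids: Sequence[str]) -> dict[str, tuple[float, Optional[str]]]:
    """Per column: the largest absolute correlation with any other column."""
    out: dict[str, tuple[float, Optional[str]]] = {i: (0.0, None) for i in ids}
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    for i, id_i in enumerate(ids):
        best, partner = 0.0, None
        for j, id_j in enumerate(ids):
            if i == j or not np.isfinite(corr[i, j]):
                continue
            if abs(corr[i, j]) > best:
                best, partner = abs(float(corr[i, j])), id_j
        out[id_i] = (best, partner)
    return out


def item_retention_screen(
    cohort: Sequence[ResponseRecord],
    bank: ItemBank,
    thresholds: RetentionThresholds = RetentionThresholds(),
) -> list[ItemDiagnostics]:
    """Flag items for retention review; nothing is deleted here.

    Knowledge items are flagged too-easy when the proportion correct
    exceeds the difficulty threshold.  Goals are flagged for ceiling when
    the share of top-of-scale ratings exceeds its threshold, but a
    ceiling-flagged goal keeps a RETAIN flag if enough respondents name it
    among their top three; goals below the top-three minimum are flagged
    DROP.  High inter-item correlation flags redundancy on either scale.
    """
    if len(cohort) < thresholds.min_cohort:
        raise ValueError(
            f"retention screen needs at least {thresholds.min_cohort} respondents, "
            f"got {len(cohort)}"
        )
    n = len(cohort)
    out: list[ItemDiagnostics] = []

    correct = np.array(
        [
            [
                1.0 if rec.knowledge_responses.get(it.item_id) == it.correct_option else 0.0
                for it in bank.knowledge_items
            ]
            for rec in cohort
        ]
    )
    k_redund = _pairwise_max_corr(correct, bank.item_ids)
    for j, item in enumerate(bank.knowledge_items):
        difficulty = float(correct[:, j].mean())
        reasons = []
        if difficulty > thresholds.too_easy:
            reasons.append(f"too easy (difficulty {difficulty:.0%} > {thresholds.too_easy:.0%})")
        r, partner = k_redund[item.item_id]
        if r > thresholds.redundancy_r:
            reasons.append(f"redundant with {partner} (|r| = {r:.2f})")
        out.append(
            ItemDiagnostics(
                item_id=item.item_id,
                kind="knowledge",
                metric=difficulty,
                redundancy_r=r,
                redundancy_partner=partner,
                top_three_pct=None,
                flag=RetentionFlag.REVISE if reasons else RetentionFlag.RETAIN,
                reasons=tuple(reasons),
            )
        )

    ratings = np.array(
        [
            [
                np.nan if rec.goal_ratings.get(g.goal_id) is None else float(rec.goal_ratings[g.goal_id])
                for g in bank.goal_items
            ]
            for rec in cohort
        ]
    )
    complete = ratings[~np.isnan(ratings).any(axis=1)]
    g_redund = _pairwise_max_corr(complete, bank.goal_ids)
    for j, goal in enumerate(bank.goal_items):
        col = ratings[:, j]
        col = col[~np.isnan(col)]
        top_share = float((col == goal.scale_max).mean()) if col.size else 0.0
        top3 = 100.0 * sum(1 for rec in cohort if goal.goal_id in rec.top_three) / n
        reasons = []
        flag = RetentionFlag.RETAIN
        if top_share > thresholds.ceiling_share:
            reasons.append(
                f"ceiling effect ({top_share:.0%} at {goal.scale_max}/10)"
            )
            flag = RetentionFlag.REVISE
        if top3 < 100.0 * thresholds.top_three_min:
            reasons.append(
                f"rarely a top-three goal ({top3:.0f}% < {thresholds.top_three_min:.0%})"
            )
            flag = RetentionFlag.DROP
        elif top_share > thresholds.ceiling_share:
            # frequently named among the top three: keep despite ceiling
            flag = RetentionFlag.RETAIN
        r, partner = g_redund[goal.goal_id]
        if r > thresholds.redundancy_r:
            reasons.append(f"redundant with {partner} (|r| = {r:.2f})")
            if flag is RetentionFlag.RETAIN:
                flag = RetentionFlag.REVISE
        out.append(
            ItemDiagnostics(
                item_id=goal.goal_id,
                kind="goal",
                metric=top_share,
                redundancy_r=r,
                redundancy_partner=partner,
                top_three_pct=top3,
                flag=flag,
                reasons=tuple(reasons),
            )
        )
    return out


@dataclass(frozen=True)
class BriefReproducibility:
    pearson_r: Optional[float]
    n: int
    brief_icc: Optional[ICCResult]


def brief_reproducibility(
    cohort: Sequence[ResponseRecord],
    bank: ItemBank,
    retest: Optional[Sequence[ResponseRecord]] = None,
) -> BriefReproducibility:
    """Pearson correlation between the brief and full knowledge scores,
    plus the brief score's retest ICC when a retest cohort is supplied.

    Respondents contribute when both scores are defined.  A constant score
    vector makes the correlation undefined; it is reported as None.
    """
    full, brief = [], []
    for rec in cohort:
        f = score_knowledge(rec, bank)
        b = score_brief(rec, bank)
        if f.defined and b.defined:
            full.append(f.score_pct)
            brief.append(b.score_pct)
    if len(full) < 3:
        raise ValueError("need at least 3 respondents with both scores defined")
    fa, ba = np.asarray(full), np.asarray(brief)
    if fa.std() == 0 or ba.std() == 0:
        r = None
        logger.warning("constant scores; brief-full correlation undefined")
    else:
        r = float(stats.pearsonr(fa, ba).statistic)

    icc = None
    if retest is not None:
        by_id = {rec.respondent_id: rec for rec in retest}
        pairs = []
        for rec in cohort:
            other = by_id.get(rec.respondent_id)
            if other is None:
                continue
            b1, b2 = score_brief(rec, bank), score_brief(other, bank)
            if b1.defined and b2.defined:
                pairs.append((b1.score_pct, b2.score_pct))
        if len(pairs) >= 3:
            icc = retest_reliability(pairs, measure_id="brief-knowledge")
    return BriefReproducibility(pearson_r=r, n=len(full), brief_icc=icc)
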