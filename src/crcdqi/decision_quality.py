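"""Composite decision-quality indicator.

A decision is of high quality when the respondent is well-informed
(knowledge score at or above a threshold — by default the mean knowledge
score of a decision-aid reference cohort) AND their screening decision
matched the test implied by their goals.  The indicator is binary per
respondent; the cohort summary is the percentage flagged high-quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .concordance import ConcordanceResult, MatchResult
from .scoring import KnowledgeResult

__all__ = [
    "DecisionQualityResult",
    "DecisionQualitySummary",
    "dqi_threshold",
    "decision_quality_flags",
    "decision_quality_summary",
]


@dataclass(frozen=True)
class DecisionQualityResult:
    respondent_id: str
    knowledge_score: float
    informed: bool
    match: bool
    high_quality: bool
    threshold_used: float

    def __post_init__(self) -> None:
        if self.high_quality != (self.informed and self.match):
            raise ValueError(
                f"{self.respondent_id}: high_quality must equal informed AND match"
            )
        if self.informed != (self.knowledge_score >= self.threshold_used):
            raise ValueError(
                f"{self.respondent_id}: informed flag inconsistent with threshold"
            )


@dataclass(frozen=True)
class DecisionQualitySummary:
    results: tuple[DecisionQualityResult, ...]
    n_high_quality: int
    n_total: int
    pct: float
    threshold_used: float


def dqi_threshold(
    reference_cohort: Sequence[KnowledgeResult],
    override: Optional[float] = None,
) -> float:
    """The "informed" threshold: mean knowledge score of the reference
    (decision-aid) cohort, or an explicit override percentage."""
    if override is not None:
        return float(override)
    scores = [r.score_pct for r in reference_cohort if r.defined]
    if not scores:
        raise ValueError("reference cohort has no defined knowledge scores")
    return sum(scores) / len(scores)


def decision_quality_flags(
    knowledge: Sequence[KnowledgeResult],
    matches: Sequence[MatchResult],
    threshold: float,
) -> tuple[DecisionQualityResult, ...]:
    """Per-respondent composite flags.

    The "at or above" comparison uses the unrounded knowledge score, so a
    respondent exactly at the threshold counts as informed.  Knowledge and
    match inputs must cover the same respondents.
    """
    k_by_id = {r.respondent_id: r for r in knowledge if r.defined}
    m_by_id = {m.respondent_id: m for m in matches}
    only_k = sorted(set(k_by_id) - set(m_by_id))
    only_m = sorted(set(m_by_id) - set(k_by_id))
    if only_k or only_m:
        raise ValueError(
            "knowledge and concordance inputs cover different respondents: "
            f"knowledge-only={only_k}, match-only={only_m}"
        )
    out = []
    for rid in k_by_id:
        score = k_by_id[rid].score_pct
        assert score is not None
        informed = score >= threshold
        match = m_by_id[rid].match
        out.append(
            DecisionQualityResult(
                respondent_id=rid,
                knowledge_score=score,
                informed=informed,
                match=match,
                high_quality=informed and match,
                threshold_used=threshold,
            )
        )
    return tuple(out)


def decision_quality_summary(
    knowledge: Sequence[KnowledgeResult],
    concordance: ConcordanceResult | Sequence[MatchResult],
    threshold: float,
) -> DecisionQualitySummary:
    """Cohort summary: count and percentage meeting the high-quality bar."""
    matches = (
        concordance.matches
        if isinstance(concordance, ConcordanceResult)
        else tuple(concordance)
    )
    results = decision_quality_flags(knowledge, matches, threshold)
    if not results:
        raise ValueError("no respondents to summarize")
    n_hq = sum(1 for r in results if r.high_quality)
    return DecisionQualitySummary(
        results=results,
        n_high_quality=n_hq,
        n_total=len(results),
        pct=100.0 * n_hq / len(results),
        threshold_used=threshold,
    )
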