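"""Knowledge scoring under the instrument's missing-data rules.

Each correct response earns one point.  Missing responses count as
incorrect, the denominator is always the full item count, and a total
score is defined only for respondents who answered at least half of the
items; scores are standardized to 0-100%.  The same rules apply to the
five-item brief form (which therefore requires at least 3 answered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .item_bank import ItemBank, ItemBankError
from .records import ResponseRecord

__all__ = [
    "KnowledgeResult",
    "score_knowledge",
    "score_brief",
    "item_difficulty",
    "cohort_knowledge_mean",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, the convention used for all
    displayed percentages (banker's rounding would map 47.35 to 47.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KnowledgeResult:
    """Per-respondent knowledge score.

    ``score_pct`` is ``100 * n_correct / n_items`` when at least half of
    the items were answered, else ``None`` (no total score assigned).
    """

    respondent_id: str
    n_items: int
    n_answered: int
    n_correct: int
    score_pct: Optional[float]

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_answered <= self.n_items):
            raise ValueError(
                f"{self.respondent_id}: inconsistent counts "
                f"(correct={self.n_correct}, answered={self.n_answered}, items={self.n_items})"
            )

    @property
    def defined(self) -> bool:
        return self.score_pct is not None


def _min_answered(n_items: int) -> int:
    # "at least half": for an odd item count, require the strict majority
    # (ceil(n/2)); 5 items -> at least 3 answered.
    return math.ceil(n_items / 2)


def score_knowledge(record: ResponseRecord, bank: ItemBank) -> KnowledgeResult:
    """Score one respondent against every knowledge item in the bank.

    A response is correct iff its option label equals the item's keyed
    answer; missing and incorrect responses contribute zero.  The score is
    undefined when fewer than half of the items were answered.
    """
    if not bank.knowledge_items:
        raise ItemBankError("cannot score against a bank with no knowledge items")
    n_items = len(bank.knowledge_items)
    n_answered = 0
    n_correct = 0
    for item in bank.knowledge_items:
        response = record.knowledge_responses.get(item.item_id)
        if response is not None:
            n_answered += 1
            if response == item.correct_option:
                n_correct += 1
    if n_answered < _min_answered(n_items):
        score = None
    else:
        score = 100.0 * n_correct / n_items
    return KnowledgeResult(
        respondent_id=record.respondent_id,
        n_items=n_items,
        n_answered=n_answered,
        n_correct=n_correct,
        score_pct=score,
    )


def score_brief(record: ResponseRecord, bank: ItemBank) -> KnowledgeResult:
    """Score the five-item brief form with the identical rules (undefined
    when fewer than 3 of the 5 subset items were answered)."""
    return score_knowledge(record, bank.brief_bank())


def item_difficulty(
    cohort: Sequence[ResponseRecord], bank: ItemBank
) -> dict[str, float]:
    """Per-item proportion correct over the cohort.

    Missing counts as incorrect and the denominator is the cohort size, so
    the values aggregate consistently with the individual scores.
    """
    if not cohort:
        raise ValueError("item_difficulty requires a nonempty cohort")
    if not bank.knowledge_items:
        raise ItemBankError("cannot compute difficulties for an empty bank")
    n = len(cohort)
    out: dict[str, float] = {}
    for item in bank.knowledge_items:
        correct = sum(
            1
            for rec in cohort
            if rec.knowledge_responses.get(item.item_id) == item.correct_option
        )
        out[item.item_id] = correct / n
    return out


def cohort_knowledge_mean(
    cohort: Sequence[ResponseRecord], bank: ItemBank
) -> float:
    """Mean knowledge score (percent) over respondents with a defined score.

    Respondents who answered fewer than half the items carry no total score
    and are excluded.  When every score is defined, this equals 100 x the
    mean per-item difficulty regardless of how correctness co-occurs across
    respondents (both sides count the same correct answers over the same
    denominator).
    """
    scores = [r.score_pct for r in (score_knowledge(rec, bank) for rec in cohort) if r.defined]
    if not scores:
        raise ValueError("no respondent has a defined knowledge score")
    return sum(scores) / len(scores)
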