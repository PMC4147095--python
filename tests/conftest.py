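"""Shared fixtures and cohort builders."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pytest

from crcdqi.item_bank import ItemBank, default_item_bank
from crcdqi.records import (
    Arm,
    Involvement,
    Mode,
    ResponseRecord,
    ScreeningHistory,
    Timepoint,
)

# Published per-item correct counts: (sample size, counts per item K01..K10)
TABLE3 = {
    "online_da": (163, [150, 109, 155, 151, 140, 147, 156, 92, 136, 133]),
    "online_control": (175, [126, 63, 168, 125, 96, 115, 160, 72, 148, 53]),
    "provider": (115, [114, 66, 113, 109, 112, 111, 113, 100, 110, 73]),
    "clinic": (94, [50, 6, 81, 55, 28, 48, 70, 21, 71, 12]),
}


@pytest.fixture(scope="session")
def bank() -> ItemBank:
    return default_item_bank()


def make_record(
    bank: ItemBank,
    respondent_id: str = "R1",
    n_correct: int = 10,
    n_wrong: int = 0,
    age: Optional[float] = 60.0,
    screening: Optional[ScreeningHistory] = ScreeningHistory.COLONOSCOPY,
    goal_ratings: Optional[dict[str, Optional[int]]] = None,
    **kwargs,
) -> ResponseRecord:
    """A record answering the first ``n_correct`` items correctly, the next
    ``n_wrong`` incorrectly, and leaving the rest missing."""
    responses: dict[str, Optional[str]] = {}
    for i, item in enumerate(bank.knowledge_items):
        if i < n_correct:
            responses[item.item_id] = item.correct_option
        elif i < n_correct + n_wrong:
            responses[item.item_id] = next(
                o for o in item.options if o != item.correct_option
            )
        else:
            responses[item.item_id] = None
    if goal_ratings is None:
        goal_ratings = {g: 5 for g in bank.goal_ids}
    return ResponseRecord(
        respondent_id=respondent_id,
        age=age,
        screening_history=screening,
        knowledge_responses=responses,
        goal_ratings=goal_ratings,
        **kwargs,
    )


def cohort_from_counts(
    bank: ItemBank,
    n: int,
    counts: Sequence[int],
    rng: Optional[np.random.Generator] = None,
    prefix: str = "C",
) -> list[ResponseRecord]:
    """A cohort of ``n`` respondents whose per-item correct counts equal
    ``counts`` exactly; which respondents are correct on each item is
    either deterministic (first k) or randomized via ``rng``."""
    assert len(counts) == len(bank.knowledge_items)
    correct_sets = []
    for k in counts:
        assert 0 <= k <= n
        who = np.arange(n) if rng is None else rng.permutation(n)
        correct_sets.append(set(who[:k].tolist()))
    cohort = []
    for i in range(n):
        responses: dict[str, Optional[str]] = {}
        for j, item in enumerate(bank.knowledge_items):
            if i in correct_sets[j]:
                responses[item.item_id] = item.correct_option
            else:
                responses[item.item_id] = next(
                    o for o in item.options if o != item.correct_option
                )
        cohort.append(
            ResponseRecord(
                respondent_id=f"{prefix}{i:04d}",
                knowledge_responses=responses,
                goal_ratings={g: 5 for g in bank.goal_ids},
            )
        )
    return cohort
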