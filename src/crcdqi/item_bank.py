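"""Instrument definition: knowledge items, goals, and configured subsets.

The CRC-DQI item bank holds the retained multiple-choice knowledge items
with their keyed answers, the goals-and-concerns rated for importance on a
0-10 scale, the subset of goals used as preference-model covariates, and a
five-item brief-version subset.  Banks are loaded from a YAML config; the
packaged default bank ships the published 10-item / 8-goal instrument.

Knowledge responses are stored and compared as option *labels*, never as
positions, so reordering options in a config cannot silently change scoring.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

if TYPE_CHECKING:  # pragma: no cover
    from .records import ResponseRecord

__all__ = [
    "KnowledgeItem",
    "GoalItem",
    "ItemBank",
    "ItemBankError",
    "ValidationFinding",
    "load_item_bank",
    "default_item_bank",
    "validate_response",
]


class ItemBankError(ValueError):
    """Raised when an item-bank config violates an invariant."""


class KnowledgeItem(BaseModel):
    """A multiple-choice knowledge item with a single keyed answer."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    prompt: str
    options: tuple[str, ...]
    correct_option: str

    @model_validator(mode="after")
    def _key_in_options(self) -> "KnowledgeItem":
        if self.correct_option not in self.options:
            raise ValueError(
                f"item {self.item_id!r}: correct_option {self.correct_option!r} "
                f"is not among its options"
            )
        return self


class GoalItem(BaseModel):
    """A goal/concern rated on an importance scale.

    The scale runs from ``scale_min`` ("not at all important") to
    ``scale_max`` ("extremely important"); the instrument uses 0-10.
    """

    model_config = ConfigDict(frozen=True)

    goal_id: str
    prompt: str
    scale_min: int = 0
    scale_max: int = 10

    @model_validator(mode="after")
    def _scale_ordered(self) -> "GoalItem":
        if self.scale_min >= self.scale_max:
            raise ValueError(f"goal {self.goal_id!r}: degenerate rating scale")
        return self


class ItemBank(BaseModel):
    """The full instrument definition.

    Invariants enforced at construction: unique item and goal ids, a
    five-member brief subset drawn from the knowledge items, and model
    goals drawn from the goal list.
    """

    model_config = ConfigDict(frozen=True)

    knowledge_items: tuple[KnowledgeItem, ...]
    goal_items: tuple[GoalItem, ...]
    brief_subset: tuple[str, ...]
    model_goals: tuple[str, ...]

    @field_validator("knowledge_items")
    @classmethod
    def _unique_items(cls, v):
        ids = [it.item_id for it in v]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate knowledge item_id(s): {dupes}")
        return v

    @field_validator("goal_items")
    @classmethod
    def _unique_goals(cls, v):
        ids = [g.goal_id for g in v]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate goal_id(s): {dupes}")
        return v

    @model_validator(mode="after")
    def _subsets_consistent(self) -> "ItemBank":
        item_ids = {it.item_id for it in self.knowledge_items}
        goal_ids = {g.goal_id for g in self.goal_items}
        if len(self.brief_subset) != 5:
            raise ValueError(
                f"brief_subset must have exactly 5 members, got {len(self.brief_subset)}"
            )
        missing = [i for i in self.brief_subset if i not in item_ids]
        if missing:
            raise ValueError(f"brief_subset ids not in knowledge_items: {missing}")
        missing = [g for g in self.model_goals if g not in goal_ids]
        if missing:
            raise ValueError(f"model_goals ids not in goal_items: {missing}")
        return self

    # -- convenience lookups -------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.knowledge_items)

    @property
    def goal_ids(self) -> tuple[str, ...]:
        return tuple(g.goal_id for g in self.goal_items)

    def item(self, item_id: str) -> KnowledgeItem:
        for it in self.knowledge_items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def goal(self, goal_id: str) -> GoalItem:
        for g in self.goal_items:
            if g.goal_id == goal_id:
                return g
        raise KeyError(goal_id)

    def brief_bank(self) -> "ItemBank":
        """The bank restricted to the brief knowledge subset."""
        kept = tuple(it for it in self.knowledge_items if it.item_id in self.brief_subset)
        return ItemBank(
            knowledge_items=kept,
            goal_items=self.goal_items,
            brief_subset=self.brief_subset,
            model_goals=self.model_goals,
        )

    def to_config(self) -> dict:
        """Plain-dict form suitable for YAML round-tripping."""
        return {
            "knowledge_items": [
                {
                    "item_id": it.item_id,
                    "prompt": it.prompt,
                    "options": list(it.options),
                    "correct_option": it.correct_option,
                }
                for it in self.knowledge_items
            ],
            "goal_items": [
                {
                    "goal_id": g.goal_id,
                    "prompt": g.prompt,
                    "scale_min": g.scale_min,
                    "scale_max": g.scale_max,
                }
                for g in self.goal_items
            ],
            "model_goals": list(self.model_goals),
            "brief_subset": list(self.brief_subset),
        }


def load_item_bank(config: Union[str, Path, dict]) -> ItemBank:
    """Load and validate an item bank from a YAML path or a config mapping.

    Raises :class:`ItemBankError` naming the offending field when the config
    violates a bank invariant (duplicate ids, key absent from options,
    brief subset not of size 5, ...).
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ItemBankError("item-bank config must be a mapping")
    try:
        return ItemBank(**config)
    except (ValueError, TypeError) as exc:
        raise ItemBankError(str(exc)) from exc


def default_item_bank() -> ItemBank:
    """The packaged default bank: 10 knowledge items and 8 goals."""
    ref = resources.files("crcdqi.data").joinpath("default_bank.yaml")
    return load_item_bank(yaml.safe_load(ref.read_text(encoding="utf-8")))


class ValidationFinding(BaseModel):
    """One problem found in a response record (findings, not exceptions)."""

    model_config = ConfigDict(frozen=True)

    respondent_id: str
    field: str
    message: str


def validate_response(record: "ResponseRecord", bank: ItemBank) -> list[ValidationFinding]:
    """Check one response record against the bank.

    Returns a list of findings covering unknown item/goal ids, knowledge
    responses not among an item's options, and goal ratings outside the
    importance scale.  An empty list means the record is clean.
    """
    findings: list[ValidationFinding] = []
    rid = record.respondent_id
    item_ids = set(bank.item_ids)
    goal_ids = set(bank.goal_ids)

    for item_id, response in record.knowledge_responses.items():
        if item_id not in item_ids:
            findings.append(
                ValidationFinding(
                    respondent_id=rid,
                    field=item_id,
                    message=f"unknown knowledge item {item_id!r}",
                )
            )
            continue
        if response is not None and response not in bank.item(item_id).options:
            findings.append(
                ValidationFinding(
                    respondent_id=rid,
                    field=item_id,
                    message=f"response {response!r} not among options for {item_id}",
                )
            )

    for goal_id, rating in record.goal_ratings.items():
        if goal_id not in goal_ids:
            findings.append(
                ValidationFinding(
                    respondent_id=rid,
                    field=goal_id,
                    message=f"unknown goal {goal_id!r}",
                )
            )
            continue
        goal = bank.goal(goal_id)
        if rating is not None and not (goal.scale_min <= rating <= goal.scale_max):
            findings.append(
                ValidationFinding(
                    respondent_id=rid,
                    field=goal_id,
                    message=(
                        f"rating {rating} outside importance scale "
                        f"[{goal.scale_min}, {goal.scale_max}]"
                    ),
                )
            )

    for goal_id in record.top_three:
        if goal_id not in goal_ids:
            findings.append(
                ValidationFinding(
                    respondent_id=rid,
                    field="top_three",
                    message=f"top-three goal {goal_id!r} not in bank",
                )
            )

    return findings
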