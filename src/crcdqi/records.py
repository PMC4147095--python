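"""Respondent-level data containers shared across the scoring pipeline."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Timepoint",
    "Arm",
    "Mode",
    "ScreeningHistory",
    "DecisionMaker",
    "Involvement",
    "ResponseRecord",
]


class Timepoint(str, enum.Enum):
    TEST = "test"
    RETEST = "retest"


class Arm(str, enum.Enum):
    """Randomization arm: decision-aid recipients, controls, or not randomized."""

    DECISION_AID = "decision_aid"
    CONTROL = "control"
    NONE = "none"


class Mode(str, enum.Enum):
    ONLINE = "online"
    MAIL = "mail"
    IN_PERSON = "in_person"


class ScreeningHistory(str, enum.Enum):
    NEVER = "never"
    COLONOSCOPY = "colonoscopy"
    OTHER_TEST = "other_test"


class DecisionMaker(str, enum.Enum):
    PATIENT = "patient"
    DOCTOR = "doctor"
    SHARED = "shared"


@dataclass(frozen=True)
class Involvement:
    """Self-reported involvement: who made the decision, and how involved."""

    decision_maker: Optional[DecisionMaker] = None
    involvement_level: Optional[int] = None  # ordinal, higher = more involved


@dataclass
class ResponseRecord:
    """One respondent at one timepoint.

    ``knowledge_responses`` maps item_id to the selected option label
    (``None`` = missing); ``goal_ratings`` maps goal_id to an integer
    importance rating 0-10 (``None`` = missing).  ``top_three`` holds up
    to three goal_ids the respondent named most important.
    """

    respondent_id: str
    timepoint: Timepoint = Timepoint.TEST
    arm: Arm = Arm.NONE
    mode: Mode = Mode.ONLINE
    age: Optional[float] = None
    sex: Optional[str] = None
    education: Optional[str] = None
    race: Optional[str] = None
    screening_history: Optional[ScreeningHistory] = None
    knowledge_responses: dict[str, Optional[str]] = field(default_factory=dict)
    goal_ratings: dict[str, Optional[int]] = field(default_factory=dict)
    top_three: frozenset[str] = field(default_factory=frozenset)
    involvement: Involvement = field(default_factory=Involvement)

    def __post_init__(self) -> None:
        # out-of-range ratings are left in place for validate_response to
        # report as findings; only the structural top-three cap is enforced
        if len(self.top_three) > 3:
            raise ValueError(
                f"{self.respondent_id}: top_three has {len(self.top_three)} members (max 3)"
            )
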