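"""Delimited-text I/O for respondent records and rendered reports.

The response file is a UTF-8 CSV with a required header row; one row per
respondent per timepoint; an empty field means missing.  Knowledge columns
carry option labels (K01...), goal columns integer ratings 0-10 (G_...),
and ``top_three`` a semicolon-separated list of goal ids.  The round trip
write -> read is lossless for every field including missingness.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .item_bank import ItemBank
from .records import (
    Arm,
    DecisionMaker,
    Involvement,
    Mode,
    ResponseRecord,
    ScreeningHistory,
    Timepoint,
)
from .scoring import round_half_up

__all__ = ["ResponseFileError", "read_responses", "write_responses", "write_report"]

logger = logging.getLogger(__name__)

_FIXED_COLUMNS = [
    "respondent_id",
    "timepoint",
    "arm",
    "mode",
    "age",
    "sex",
    "education",
    "race",
    "screening_history",
    "top_three",
    "decision_maker",
    "involvement_level",
]


class ResponseFileError(ValueError):
    """Malformed response file; the message names the row and column."""


def _blank(value) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "")


def _parse_enum(enum_cls, value, row: int, column: str):
    if _blank(value):
        return None
    try:
        return enum_cls(value.strip())
    except ValueError as exc:
        allowed = [e.value for e in enum_cls]
        raise ResponseFileError(
            f"row {row}, column {column!r}: {value!r} not one of {allowed}"
        ) from exc


def read_responses(
    path: Union[str, Path], bank: ItemBank
) -> list[ResponseRecord]:
    """Read a response CSV into validated records.

    Malformed values raise :class:`ResponseFileError` naming the row and
    column; columns not in the schema are reported as warnings and
    ignored.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(_FIXED_COLUMNS) | set(bank.item_ids) | set(bank.goal_ids)
    for col in df.columns:
        if col not in known:
            logger.warning("%s: unknown column %r ignored", path, col)
    if "respondent_id" not in df.columns:
        raise ResponseFileError("missing required column 'respondent_id'")

    records: list[ResponseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row_d = dict(zip(df.columns, row))
        rid = row_d.get("respondent_id", "")
        if _blank(rid):
            raise ResponseFileError(f"row {i}: empty respondent_id")

        def _num(column: str, conv, lo=None, hi=None):
            raw = row_d.get(column, "")
            if _blank(raw):
                return None
            try:
                val = conv(raw)
            except ValueError as exc:
                raise ResponseFileError(
                    f"row {i}, column {column!r}: {raw!r} is not a number"
                ) from exc
            if lo is not None and not (lo <= val <= hi):
                raise ResponseFileError(
                    f"row {i}, column {column!r}: {val} outside [{lo}, {hi}]"
                )
            return val

        knowledge = {
            item_id: (None if _blank(row_d.get(item_id)) else row_d[item_id].strip())
            for item_id in bank.item_ids
            if item_id in df.columns
        }
        goals = {
            goal_id: _num(goal_id, lambda s: int(float(s)), 0, 10)
            for goal_id in bank.goal_ids
            if goal_id in df.columns
        }
        top_raw = row_d.get("top_three", "")
        top = frozenset() if _blank(top_raw) else frozenset(
            t.strip() for t in top_raw.split(";") if t.strip()
        )
        if len(top) > 3:
            raise ResponseFileError(
                f"row {i}, column 'top_three': {len(top)} goals listed (max 3)"
            )
        try:
            rec = ResponseRecord(
                respondent_id=rid.strip(),
                timepoint=_parse_enum(Timepoint, row_d.get("timepoint"), i, "timepoint")
                or Timepoint.TEST,
                arm=_parse_enum(Arm, row_d.get("arm"), i, "arm") or Arm.NONE,
                mode=_parse_enum(Mode, row_d.get("mode"), i, "mode") or Mode.ONLINE,
                age=_num("age", float),
                sex=None if _blank(row_d.get("sex")) else row_d["sex"].strip(),
                education=None if _blank(row_d.get("education")) else row_d["education"].strip(),
                race=None if _blank(row_d.get("race")) else row_d["race"].strip(),
                screening_history=_parse_enum(
                    ScreeningHistory, row_d.get("screening_history"), i, "screening_history"
                ),
                knowledge_responses=knowledge,
                goal_ratings=goals,
                top_three=top,
                involvement=Involvement(
                    decision_maker=_parse_enum(
                        DecisionMaker, row_d.get("decision_maker"), i, "decision_maker"
                    ),
                    involvement_level=_num("involvement_level", lambda s: int(float(s))),
                ),
            )
        except ValueError as exc:
            raise ResponseFileError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_responses(
    records: Sequence[ResponseRecord], path: Union[str, Path], bank: ItemBank
) -> None:
    """Write records to the response CSV dialect (empty field = missing)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "respondent_id": rec.respondent_id,
            "timepoint": rec.timepoint.value,
            "arm": rec.arm.value,
            "mode": rec.mode.value,
            "age": "" if rec.age is None else repr(rec.age),
            "sex": rec.sex or "",
            "education": rec.education or "",
            "race": rec.race or "",
            "screening_history": (
                "" if rec.screening_history is None else rec.screening_history.value
            ),
            "top_three": ";".join(sorted(rec.top_three)),
            "decision_maker": (
                ""
                if rec.involvement.decision_maker is None
                else rec.involvement.decision_maker.value
            ),
            "involvement_level": (
                ""
                if rec.involvement.involvement_level is None
                else rec.involvement.involvement_level
            ),
        }
        for item_id in bank.item_ids:
            response = rec.knowledge_responses.get(item_id)
            row[item_id] = "" if response is None else response
        for goal_id in bank.goal_ids:
            rating = rec.goal_ratings.get(goal_id)
            row[goal_id] = "" if rating is None else rating
        rows.append(row)
    columns = _FIXED_COLUMNS + list(bank.item_ids) + list(bank.goal_ids)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_report(
    tables: dict[str, pd.DataFrame],
    summary_lines: Sequence[str],
    out_dir: Union[str, Path],
    fmt: str = "csv",
) -> list[Path]:
    """Emit machine-readable tables (full precision) plus a human-readable
    summary (display rounding only here).  Returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if fmt == "md":
            p = out / f"{name}.md"
            p.write_text(df.to_markdown(index=False) + "\n", encoding="utf-8")
        else:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
        written.append(p)
    p = out / "summary.md"
    p.write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
    written.append(p)
    return written


def render_item_table(difficulties: dict[str, float], n: int) -> pd.DataFrame:
    """Per-item correct counts and percentages in the published table layout."""
    rows = [
        {
            "item_id": item_id,
            "n_correct": int(round(p * n)),
            "pct_correct": round_half_up(100.0 * p),
        }
        for item_id, p in difficulties.items()
    ]
    return pd.DataFrame(rows)
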