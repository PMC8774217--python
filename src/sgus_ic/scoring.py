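"""S-GUS questionnaire scoring.

The short-form Global Usability Score (S-GUS) is a 12-item instrument
yielding a 0-50 usability score per inhaler (higher = more usable).
Items 1-9 carry a single subscore each, items 10 and 11 are graded by
the degree of difficulty the patient objectively shows (strictly
decreasing subscores), and item 12 scores a fixed constant (3.2 by
default) when the patient's self-assessment agrees with the supervising
nurse's judgment, else 0.

The published instrument's full per-item subscore table is not public;
the shipped default configuration is a documented stand-in that honours
every published constraint (maximum total 50, item-12 agreement value
3.2, strictly decreasing difficulty grades) and is fully overridable
via a YAML/JSON file, see :func:`load_scoring_config`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Item",
    "ItemResponse",
    "DeviceScore",
    "ScoringConfig",
    "ScoringError",
    "default_scoring_config",
    "load_scoring_config",
    "validate_config",
    "score_device",
    "score_cohort",
]

KIND_SINGLE = "single"
KIND_DIFFICULTY = "difficulty"
KIND_AGREEMENT = "agreement"

_VALID_KINDS = (KIND_SINGLE, KIND_DIFFICULTY, KIND_AGREEMENT)


class ScoringError(ValueError):
    """Raised for malformed responses (missing/duplicate item, unknown level)."""


@dataclass(frozen=True)
class Item:
    """One questionnaire item.

    ``levels`` maps each allowed categorical response code to its
    subscore in points; the mapping order is the instrument's order
    (for difficulty items: easiest first, so subscores decrease).
    """

    item_id: int
    kind: str
    levels: Mapping[str, float]

    @property
    def max_subscore(self) -> float:
        return max(self.levels.values())

    def subscore(self, level: str) -> float:
        if level not in self.levels:
            raise ScoringError(
                f"item {self.item_id}: unknown response level {level!r}; "
                f"allowed: {sorted(self.levels)}"
            )
        return float(self.levels[level])


@dataclass(frozen=True)
class ItemResponse:
    patient_id: str
    device_id: str
    item_id: int
    level: str


@dataclass(frozen=True)
class DeviceScore:
    """Total S-GUS for one patient-device pair, in points on [0, 50]."""

    patient_id: str
    device_id: str
    sgus_total: float


@dataclass(frozen=True)
class ScoringConfig:
    items: tuple[Item, ...]
    agreement_value: float = 3.2

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def max_total(self) -> float:
        return float(sum(it.max_subscore for it in self.items))


def default_scoring_config() -> ScoringConfig:
    """The shipped 12-item configuration (documented stand-in).

    Items 1-3 (previous device experience): 2.0 points each.
    Items 4-9 ("at a glance" preference/satisfaction): 3.0 points each.
    Item 10 (handling difficulty, nurse-observed): 10.0 / 6.6 / 3.3 / 0.
    Item 11 (actuation difficulty, nurse-observed): 12.8 / 8.5 / 4.3 / 0.
    Item 12 (patient-nurse agreement): 3.2 / 0.
    Maxima sum to exactly 50 points.
    """
    difficulty_levels_10 = {"none": 10.0, "mild": 6.6, "moderate": 3.3, "severe": 0.0}
    difficulty_levels_11 = {"none": 12.8, "mild": 8.5, "moderate": 4.3, "severe": 0.0}
    items = []
    for i in range(1, 4):
        items.append(Item(i, KIND_SINGLE, {"yes": 2.0, "no": 0.0}))
    for i in range(4, 10):
        items.append(Item(i, KIND_SINGLE, {"yes": 3.0, "no": 0.0}))
    items.append(Item(10, KIND_DIFFICULTY, difficulty_levels_10))
    items.append(Item(11, KIND_DIFFICULTY, difficulty_levels_11))
    items.append(Item(12, KIND_AGREEMENT, {"yes": 3.2, "no": 0.0}))
    return ScoringConfig(items=tuple(items), agreement_value=3.2)


def load_scoring_config(path: str | Path) -> ScoringConfig:
    """Load a ScoringConfig from YAML or JSON.

    Schema::

        agreement_value: 3.2
        items:
          - item_id: 1
            kind: single          # single | difficulty | agreement
            levels: {yes: 2.0, no: 0.0}
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)

    def level_key(k) -> str:
        # YAML 1.1 reads bare yes/no as booleans; map them back
        if isinstance(k, bool):
            return "yes" if k else "no"
        return str(k)

    items = tuple(
        Item(
            item_id=int(raw["item_id"]),
            kind=str(raw["kind"]),
            levels={level_key(k): float(v) for k, v in raw["levels"].items()},
        )
        for raw in data["items"]
    )
    return ScoringConfig(items=items, agreement_value=float(data.get("agreement_value", 3.2)))


def validate_config(config: ScoringConfig) -> list[str]:
    """Check the instrument invariants; return a (possibly empty) list of violations.

    Rules: exactly 12 items with ids 1..12; item maxima sum to 50;
    item 12 scores {agreement_value, 0}; difficulty-graded items have
    strictly decreasing subscores; no negative subscores; kinds known.
    """
    violations: list[str] = []
    ids = [it.item_id for it in config.items]
    if sorted(ids) != list(range(1, 13)):
        violations.append(
            f"config must contain exactly items 1..12 once each, got ids {sorted(ids)}"
        )
    if abs(config.max_total - 50.0) > 1e-9:
        violations.append(f"item maxima must sum to 50, got {config.max_total:g}")
    for it in config.items:
        if it.kind not in _VALID_KINDS:
            violations.append(f"item {it.item_id}: unknown kind {it.kind!r}")
        if any(v < 0 for v in it.levels.values()):
            violations.append(f"item {it.item_id}: negative subscores are not allowed")
        if it.kind == KIND_AGREEMENT:
            scores = sorted(it.levels.values(), reverse=True)
            if len(scores) != 2 or scores[1] != 0.0 or abs(
                scores[0] - config.agreement_value
            ) > 1e-9:
                violations.append(
                    f"item {it.item_id} must score agreement_value "
                    f"({config.agreement_value:g}) or 0"
                )
        if it.kind == KIND_DIFFICULTY:
            vals = list(it.levels.values())
            if any(a <= b for a, b in zip(vals, vals[1:])):
                violations.append(
                    f"item {it.item_id}: difficulty subscores must strictly decrease"
                )
    return violations


def score_device(
    responses: Iterable[ItemResponse], config: ScoringConfig
) -> DeviceScore:
    """Score one patient-device record: total = sum of item subscores.

    Requires exactly one response per item 1..12; raises
    :class:`ScoringError` naming the offending item otherwise.
    """
    responses = list(responses)
    if not responses:
        raise ScoringError("no responses supplied")
    pids = {r.patient_id for r in responses}
    dids = {r.device_id for r in responses}
    if len(pids) != 1 or len(dids) != 1:
        raise ScoringError(
            f"responses must belong to a single patient-device pair, got "
            f"patients {sorted(pids)}, devices {sorted(dids)}"
        )
    seen: dict[int, str] = {}
    for r in responses:
        if r.item_id in seen:
            raise ScoringError(f"duplicate response for item {r.item_id}")
        seen[r.item_id] = r.level
    expected = {it.item_id for it in config.items}
    missing = sorted(expected - set(seen))
    if missing:
        raise ScoringError(f"missing response for item(s) {missing}")
    extra = sorted(set(seen) - expected)
    if extra:
        raise ScoringError(f"responses for unknown item(s) {extra}")
    total = sum(config.item(i).subscore(level) for i, level in seen.items())
    return DeviceScore(
        patient_id=responses[0].patient_id,
        device_id=responses[0].device_id,
        sgus_total=float(total),
    )


def score_cohort(responses: pd.DataFrame, config: ScoringConfig) -> pd.DataFrame:
    """Score a whole cohort of item responses.

    ``responses`` needs columns ``patient_id, device_id, item_id, level``;
    returns one row per (patient, device) with ``sgus_total``, sorted by
    patient then device so the output is deterministic.
    """
    required = {"patient_id", "device_id", "item_id", "level"}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ScoringError(f"responses table missing column(s) {sorted(missing_cols)}")
    out: list[DeviceScore] = []
    for (pid, did), grp in responses.groupby(["patient_id", "device_id"], sort=True):
        try:
            out.append(
                score_device(
                    [
                        ItemResponse(str(pid), str(did), int(row.item_id), str(row.level))
                        for row in grp.itertuples()
                    ],
                    config,
                )
            )
        except ScoringError as exc:
            raise ScoringError(f"patient {pid!r}, device {did!r}: {exc}") from exc
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in out],
            "device_id": [s.device_id for s in out],
            "sgus_total": [s.sgus_total for s in out],
        }
    )
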