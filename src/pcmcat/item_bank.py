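"""Item bank data model and file I/O.

An :class:`Item` is a polytomous survey question scored 0..n_steps under the
partial credit model.  Each item carries an overall difficulty (logits) and an
ordered vector of step thresholds whose mean equals the difficulty.  Items may
additionally carry a ``route_map`` implementing conditional skip logic: the
answer category chosen determines which item is presented next.  Items inside
the adaptive-testing pool never carry routes (skip items are excluded from the
pool by construction).

The bundled 24-item bank covers the ward / doctors / nurses / patient care /
treatment sections of the UK NHS adult inpatient questionnaire, with published
item difficulties and category counts.  Only the difficulty and the number of
score steps are published for these items, so step thresholds are generated by
a symmetric-spread rule: thresholds are centred on the difficulty with a fixed
spacing (default 1.0 logit), which preserves the published difficulty as the
threshold mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemBank",
    "BankValidationError",
    "symmetric_thresholds",
    "load_item_bank",
    "save_item_bank",
    "default_nhs_bank",
    "demo_routing_bank",
]

_FIXTURE = "nhs24_items.csv"


class BankValidationError(ValueError):
    """Raised when an item bank fails structural validation."""


def symmetric_thresholds(difficulty: float, n_steps: int, spacing: float = 1.0) -> tuple[float, ...]:
    """Step thresholds centred on ``difficulty`` with fixed ``spacing``.

    1 step -> [d]; 2 steps -> [d - s/2, d + s/2]; 3 steps -> [d - s, d, d + s].
    The mean of the returned thresholds equals ``difficulty``.
    """
    if n_steps < 1:
        raise BankValidationError(f"n_steps must be >= 1, got {n_steps}")
    offsets = (np.arange(n_steps) - (n_steps - 1) / 2.0) * spacing
    return tuple(float(difficulty + o) for o in offsets)


@dataclass(frozen=True)
class Item:
    """A single polytomous questionnaire item.

    Parameters
    ----------
    item_id:
        Questionnaire number (unique within a bank).
    text:
        Question wording.
    n_steps:
        Number of score steps; category scores run 0..n_steps.
    difficulty:
        Overall item difficulty in logits (mean of the step thresholds).
    step_thresholds:
        Ordered step thresholds (delta_1..delta_m) in logits.
    route_map:
        Conditional-path routing: answer category -> next item_id.  Empty for
        ordinary items, which fall through to the next item in bank order.
    in_pool:
        Whether the item belongs to the adaptive-testing pool.
    """

    item_id: int
    text: str
    n_steps: int
    difficulty: float
    step_thresholds: tuple[float, ...]
    route_map: Mapping[int, int] = field(default_factory=dict)
    in_pool: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise BankValidationError(
                f"item {self.item_id}: n_steps must be >= 1, got {self.n_steps}"
            )
        if len(self.step_thresholds) != self.n_steps:
            raise BankValidationError(
                f"item {self.item_id}: {len(self.step_thresholds)} thresholds "
                f"for n_steps={self.n_steps}"
            )
        mean = float(np.mean(self.step_thresholds))
        if abs(mean - self.difficulty) > 1e-9:
            raise BankValidationError(
                f"item {self.item_id}: mean(step_thresholds)={mean!r} != "
                f"difficulty={self.difficulty!r}"
            )
        for ans in self.route_map:
            if not (0 <= ans <= self.n_steps):
                raise BankValidationError(
                    f"item {self.item_id}: route key {ans} is not a valid "
                    f"category code (0..{self.n_steps})"
                )
        if self.in_pool and self.route_map:
            raise BankValidationError(
                f"item {self.item_id}: pool items must not carry routes"
            )

    @classmethod
    def from_difficulty(
        cls,
        item_id: int,
        difficulty: float,
        n_steps: int,
        *,
        text: str = "",
        spacing: float = 1.0,
        route_map: Mapping[int, int] | None = None,
        in_pool: bool = True,
    ) -> "Item":
        """Construct an item generating thresholds by the symmetric-spread rule."""
        return cls(
            item_id=item_id,
            text=text,
            n_steps=n_steps,
            difficulty=float(difficulty),
            step_thresholds=symmetric_thresholds(difficulty, n_steps, spacing),
            route_map=dict(route_map or {}),
            in_pool=in_pool,
        )

    @property
    def max_score(self) -> int:
        return self.n_steps


class ItemBank:
    """Ordered collection of items in questionnaire order."""

    def __init__(self, items: Sequence[Item]):
        self.items: tuple[Item, ...] = tuple(items)
        self._by_id: dict[int, Item] = {}
        for it in self.items:
            if it.item_id in self._by_id:
                raise BankValidationError(f"duplicate item_id {it.item_id}")
            self._by_id[it.item_id] = it
        for it in self.items:
            for ans, target in it.route_map.items():
                if target not in self._by_id:
                    raise BankValidationError(
                        f"item {it.item_id}: route {ans}->{target} points "
                        "outside the bank"
                    )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item_id: int) -> bool:
        return item_id in self._by_id

    def __getitem__(self, item_id: int) -> Item:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"item_id {item_id} not in bank") from None

    @property
    def pool_ids(self) -> tuple[int, ...]:
        """Ordered item_ids of the adaptive-testing pool."""
        return tuple(it.item_id for it in self.items if it.in_pool)

    def pool_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.in_pool)

    def next_in_order(self, item_id: int) -> int | None:
        """The item after ``item_id`` in questionnaire order, or None at the end."""
        ids = [it.item_id for it in self.items]
        i = ids.index(item_id)
        return ids[i + 1] if i + 1 < len(ids) else None


def _parse_routes(cell: str) -> dict[int, int]:
    # "1:40;2:41" -> {1: 40, 2: 41}
    routes: dict[int, int] = {}
    for pair in str(cell).split(";"):
        pair = pair.strip()
        if not pair:
            continue
        ans, _, target = pair.partition(":")
        routes[int(ans)] = int(target)
    return routes


def _format_routes(route_map: Mapping[int, int]) -> str:
    return ";".join(f"{a}:{t}" for a, t in sorted(route_map.items()))


def _item_from_record(rec: Mapping, row_label, spacing: float) -> Item:
    try:
        item_id = int(rec["item_id"])
        n_steps = int(rec["n_steps"])
        difficulty = float(rec["difficulty"])
    except (KeyError, TypeError, ValueError) as exc:
        raise BankValidationError(f"row {row_label}: {exc}") from exc
    if n_steps < 1:
        raise BankValidationError(f"row {row_label}: n_steps must be >= 1, got {n_steps}")

    raw_thr = rec.get("thresholds")
    if raw_thr is None or (isinstance(raw_thr, float) and np.isnan(raw_thr)) or raw_thr == "":
        thresholds = symmetric_thresholds(difficulty, n_steps, spacing)
    elif isinstance(raw_thr, str):
        thresholds = tuple(float(t) for t in raw_thr.split(";") if t.strip())
    else:
        thresholds = tuple(float(t) for t in raw_thr)

    raw_routes = rec.get("routes")
    if raw_routes is None or (isinstance(raw_routes, float) and np.isnan(raw_routes)) or raw_routes == "":
        routes: Mapping[int, int] = {}
    elif isinstance(raw_routes, str):
        routes = _parse_routes(raw_routes)
    else:
        routes = {int(k): int(v) for k, v in dict(raw_routes).items()}

    in_pool = rec.get("in_pool", 1)
    try:
        return Item(
            item_id=item_id,
            text=str(rec.get("text", "") or ""),
            n_steps=n_steps,
            difficulty=difficulty,
            step_thresholds=thresholds,
            route_map=routes,
            in_pool=bool(int(in_pool)),
        )
    except BankValidationError as exc:
        raise BankValidationError(f"row {row_label}: {exc}") from exc


def load_item_bank(
    path: str | Path,
    format: str | None = None,
    *,
    spacing: float = 1.0,
) -> ItemBank:
    """Load an item bank from a delimited (CSV) or structured (JSON) file.

    Columns / keys: item_id, text, n_steps, difficulty, thresholds
    (semicolon-joined, optional -- generated by the symmetric-spread rule if
    absent), in_pool, routes ("answer:target" pairs, semicolon-joined,
    optional).  Rows are preserved in file (questionnaire) order.
    """
    path = Path(path)
    if format is None:
        format = "structured" if path.suffix.lower() == ".json" else "delimited"
    if format == "delimited":
        frame = pd.read_csv(path, dtype={"thresholds": str, "routes": str})
        records = frame.to_dict(orient="records")
    elif format == "structured":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        records = payload["items"] if isinstance(payload, dict) else payload
    else:
        raise ValueError(f"unknown format {format!r}")
    items = [_item_from_record(rec, i + 1, spacing) for i, rec in enumerate(records)]
    return ItemBank(items)


def save_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write a bank to CSV or JSON; a reload reproduces every field."""
    path = Path(path)
    if format is None:
        format = "structured" if path.suffix.lower() == ".json" else "delimited"
    records = [
        {
            "item_id": it.item_id,
            "text": it.text,
            "n_steps": it.n_steps,
            "difficulty": it.difficulty,
            "thresholds": ";".join(repr(t) for t in it.step_thresholds),
            "in_pool": int(it.in_pool),
            "routes": _format_routes(it.route_map),
        }
        for it in bank
    ]
    if format == "delimited":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    elif format == "structured":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"items": records}, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def default_nhs_bank(spacing: float = 1.0) -> ItemBank:
    """The bundled 24-item inpatient-experience pool (questionnaire items 15-38).

    Difficulties and category counts are the published calibration; step
    thresholds are generated by the symmetric-spread rule with the given
    spacing (logits).
    """
    with resources.as_file(resources.files("pcmcat.data") / _FIXTURE) as p:
        return load_item_bank(p, "delimited", spacing=spacing)


def demo_routing_bank(spacing: float = 1.0) -> ItemBank:
    """The 24-item pool plus three synthetic skip-logic items (39-41).

    Item 39 is a conditional-path (skip) item: answer 1 routes to item 40,
    answer 2 routes to item 41.  Items 39-41 are synthetic demonstration
    items, not part of the adaptive pool, mirroring how branching questions
    sit outside the pool in the full questionnaire.
    """
    items = list(default_nhs_bank(spacing))
    items.append(
        Item.from_difficulty(
            39, 0.0, 2,
            text="Did a member of staff explain the next questions apply to you? (synthetic demo)",
            spacing=spacing, route_map={1: 40, 2: 41}, in_pool=False,
        )
    )
    items.append(
        Item.from_difficulty(
            40, -0.3, 2,
            text="Follow-up asked when the answer above was 1 (synthetic demo)",
            spacing=spacing, in_pool=False,
        )
    )
    items.append(
        Item.from_difficulty(
            41, 0.4, 1,
            text="Follow-up asked when the answer above was 2 (synthetic demo)",
            spacing=spacing, in_pool=False,
        )
    )
    return ItemBank(items)
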