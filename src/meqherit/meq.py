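"""Horne–Östberg Morningness–Eveningness Questionnaire (MEQ) scoring.

The MEQ is a 19-item self-report instrument measuring diurnal preference
(chronotype). Fifteen items are multiple-choice with fixed point values;
four (questions 1, 2, 10 and 18) are visual time scales on which the
respondent marks a preferred clock time, scored by the band of the scale
the mark falls in. The total score ranges from 16 (extreme evening
preference) to 86 (extreme morning preference) and is classified into the
five-band typology published with the scale.

The instrument itself is data, not code: the packaged fixture
``data/meq_horne_ostberg_1976.yaml`` encodes the canonical English item
texts, option point values and time-scale bands, and alternative versions
(e.g. translations with identical scoring) can be loaded from a file of the
same format. Time scales are expanded to 15-minute tick options; times past
midnight are represented as decimal hours > 24 (01:30 -> 25.5) so that
cohort mean bedtimes remain meaningful.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "Chronotype",
    "MEQItem",
    "MEQRecord",
    "MEQError",
    "load_instrument",
    "score_meq",
    "classify_score",
    "preferred_times",
    "score_responses_table",
    "read_responses_csv",
]

SCORE_MIN = 16
SCORE_MAX = 86
N_ITEMS = 19

#: Typology bands published with the scale: (low, high, category), inclusive.
CATEGORY_BANDS = (
    (16, 30, "definitely_evening"),
    (31, 41, "moderately_evening"),
    (42, 58, "intermediate"),
    (59, 69, "moderately_morning"),
    (70, 86, "definitely_morning"),
)


class Chronotype(str, enum.Enum):
    definitely_evening = "definitely_evening"
    moderately_evening = "moderately_evening"
    intermediate = "intermediate"
    moderately_morning = "moderately_morning"
    definitely_morning = "definitely_morning"


class MEQError(ValueError):
    """Invalid instrument definition, response vector or score."""


@dataclass(frozen=True)
class MEQItem:
    """One questionnaire item with its ordered answer options.

    ``option_times`` is populated only for time-scale items and holds the
    decimal-hour value of each tick option (a tick is a degenerate time
    range, so its midpoint is the tick itself).
    """

    index: int
    kind: str  # "choice" or "time_scale"
    text: str
    option_labels: tuple[str, ...]
    option_scores: tuple[int, ...]
    option_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("choice", "time_scale"):
            raise MEQError(f"item {self.index}: unknown kind {self.kind!r}")
        if not self.option_scores:
            raise MEQError(f"item {self.index}: no options")
        if len(self.option_labels) != len(self.option_scores):
            raise MEQError(f"item {self.index}: labels/scores length mismatch")
        if any(not (0 <= s <= 6) for s in self.option_scores):
            raise MEQError(f"item {self.index}: option score outside 0-6")

    @property
    def max_score(self) -> int:
        return max(self.option_scores)

    @property
    def min_score(self) -> int:
        return min(self.option_scores)


@dataclass(frozen=True)
class MEQRecord:
    """A scored questionnaire for one participant."""

    individual_id: str
    responses: tuple[int, ...]  # 1-based option indices, one per item
    total: int
    category: Chronotype
    preferred_wake: float  # decimal hours, question 1
    preferred_bed: float  # decimal hours (>24 = past midnight), question 2


def _format_time(hours: float) -> str:
    h = hours % 24.0
    return f"{int(h):02d}:{int(round((h - int(h)) * 60)):02d}"


def _expand_time_scale(spec: dict) -> tuple[tuple[str, ...], tuple[int, ...], tuple[float, ...]]:
    scale = spec["scale"]
    start, end, step = float(scale["start"]), float(scale["end"]), float(scale["step"])
    if step <= 0 or end <= start:
        raise MEQError(f"item {spec['index']}: degenerate time scale")
    n_ticks = int(round((end - start) / step)) + 1
    ticks = [start + k * step for k in range(n_ticks)]
    bands = spec["bands"]

    def band_score(t: float) -> int:
        for band in bands:  # boundary ticks take the first listed band
            if band["from"] <= t <= band["to"]:
                return int(band["score"])
        raise MEQError(f"item {spec['index']}: tick {t} not covered by any band")

    labels = tuple(_format_time(t) for t in ticks)
    scores = tuple(band_score(t) for t in ticks)
    return labels, scores, tuple(ticks)


def load_instrument(path=None, validate: bool = True) -> list[MEQItem]:
    """Load an instrument definition (defaults to the packaged 1976 English one).

    With ``validate`` the loaded instrument must have 19 items whose per-item
    maxima sum to 86 and minima to 16 — the scale's defining range.
    """
    if path is None:
        text = (
            resources.files("meqherit.data")
            .joinpath("meq_horne_ostberg_1976.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    items: list[MEQItem] = []
    for spec in raw["items"]:
        if spec["kind"] == "time_scale":
            labels, scores, times = _expand_time_scale(spec)
            items.append(
                MEQItem(
                    index=int(spec["index"]),
                    kind="time_scale",
                    text=spec["text"].strip(),
                    option_labels=labels,
                    option_scores=scores,
                    option_times=times,
                )
            )
        else:
            opts = spec["options"]
            items.append(
                MEQItem(
                    index=int(spec["index"]),
                    kind="choice",
                    text=spec["text"].strip(),
                    option_labels=tuple(o["label"] for o in opts),
                    option_scores=tuple(int(o["score"]) for o in opts),
                )
            )
    items.sort(key=lambda it: it.index)
    if validate:
        if len(items) != N_ITEMS:
            raise MEQError(f"instrument has {len(items)} items, expected {N_ITEMS}")
        if [it.index for it in items] != list(range(1, N_ITEMS + 1)):
            raise MEQError("item indices must be 1..19 without gaps")
        hi = sum(it.max_score for it in items)
        lo = sum(it.min_score for it in items)
        if (lo, hi) != (SCORE_MIN, SCORE_MAX):
            raise MEQError(
                f"instrument range [{lo}, {hi}] != [{SCORE_MIN}, {SCORE_MAX}]"
            )
    return items


def classify_score(total: int) -> Chronotype:
    """Map a total score onto the five-band typology (bands inclusive)."""
    if not (SCORE_MIN <= total <= SCORE_MAX):
        raise MEQError(f"total {total} outside the scale range 16-86")
    for lo, hi, name in CATEGORY_BANDS:
        if lo <= total <= hi:
            return Chronotype(name)
    raise AssertionError("bands partition 16-86")  # pragma: no cover


def score_meq(
    responses: Sequence[int],
    instrument: Sequence[MEQItem] | None = None,
    individual_id: str = "",
) -> MEQRecord:
    """Score one participant's 19 responses (1-based option indices).

    Missing (None/NaN) or out-of-range responses are refused with an error
    naming the offending item; single omissions are a data-collection
    problem, never imputed.
    """
    if instrument is None:
        instrument = load_instrument()
    if len(responses) != len(instrument):
        raise MEQError(
            f"expected {len(instrument)} responses, got {len(responses)}"
        )
    total = 0
    chosen: list[int] = []
    for item, resp in zip(instrument, responses):
        if resp is None or (isinstance(resp, float) and pd.isna(resp)):
            raise MEQError(f"item {item.index}: missing response")
        r = int(resp)
        if r != resp:
            raise MEQError(f"item {item.index}: non-integer response {resp!r}")
        if not (1 <= r <= len(item.option_scores)):
            raise MEQError(
                f"item {item.index}: response {r} outside options "
                f"1..{len(item.option_scores)}"
            )
        chosen.append(r)
        total += item.option_scores[r - 1]
    wake = instrument[0].option_times[chosen[0] - 1]
    bed = instrument[1].option_times[chosen[1] - 1]
    return MEQRecord(
        individual_id=str(individual_id),
        responses=tuple(chosen),
        total=total,
        category=classify_score(total),
        preferred_wake=wake,
        preferred_bed=bed,
    )


def preferred_times(record: MEQRecord) -> tuple[float, float]:
    """(preferred wake, preferred bed) in decimal hours for a scored record."""
    return record.preferred_wake, record.preferred_bed


def read_responses_csv(path) -> pd.DataFrame:
    """Read a responses table: individual_id, q1..q19 (1-based option indices)."""
    df = pd.read_csv(path)
    required = ["individual_id"] + [f"q{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MEQError(f"responses file missing columns: {', '.join(missing)}")
    return df


def score_responses_table(
    df: pd.DataFrame, instrument: Sequence[MEQItem] | None = None
) -> pd.DataFrame:
    """Score every row of a responses table.

    Returns a table with individual_id, meq_total, meq_category,
    preferred_wake, preferred_bed — the phenotype layer the downstream
    analysis consumes.
    """
    if instrument is None:
        instrument = load_instrument()
    qcols = [f"q{i}" for i in range(1, N_ITEMS + 1)]
    rows = []
    for _, row in df.iterrows():
        rec = score_meq(
            [row[c] for c in qcols], instrument, individual_id=row["individual_id"]
        )
        rows.append(
            {
                "individual_id": rec.individual_id,
                "meq_total": rec.total,
                "meq_category": rec.category.value,
                "preferred_wake": rec.preferred_wake,
                "preferred_bed": rec.preferred_bed,
            }
        )
    return pd.DataFrame(rows)
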