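"""MOS Sleep Scale item structure, response coding and summary scores.

The 12-item MOS Sleep Scale (MOS-SS) codes each of items 3-12 on a
5-category frequency scale ("All of the time" = 1 ... "None of the time"
= 5).  Items 4 and 12 describe positive experiences (feeling rested,
getting enough sleep); the remaining scored items describe negative
experiences and are reversed (``6 - r``) before summation so that higher
always means more disrupted sleep.  Two summary scores are built from
the scored items:

* **SQ** (sleep quality): items 3, 4, 5, 7, 8, 12 with 3, 5, 7, 8
  reversed; range 6 (best) .. 30 (worst).
* **DTS** (daytime sleepiness): reversed items 6, 9, 10, 11; range
  4 (best) .. 20 (worst).

Screening cut-offs of SQ >= 14 and DTS >= 9 flag clinically relevant
night-time sleep disruption and daytime sleepiness respectively.

The module also computes the conventional MOS Sleep Problems Index II
("SLP9", items 1, 3, 4, 5, 6, 7, 8, 9, 12 rescaled to a 0-100
problem-oriented mean), used as a comparator scale.  Items 1 (sleep
latency) and 2 (hours of sleep) are carried in the data model but never
enter SQ or DTS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SQ_ITEMS: tuple[int, ...] = (3, 4, 5, 7, 8, 12)
DTS_ITEMS: tuple[int, ...] = (6, 9, 10, 11)
#: negative-experience items, reversed (6 - r) before any summation
REVERSED_ITEMS: frozenset[int] = frozenset({3, 5, 6, 7, 8, 9, 10, 11})
#: positive-experience items; raw ranks are already worst-high
POSITIVE_ITEMS: frozenset[int] = frozenset({4, 12})
#: MOS Sleep Problems Index II constituents
SLP9_ITEMS: tuple[int, ...] = (1, 3, 4, 5, 6, 7, 8, 9, 12)

DEFAULT_SQ_CUTOFF = 14
DEFAULT_DTS_CUTOFF = 9

MOS_RANK_MIN, MOS_RANK_MAX = 1, 5
EORTC_RANK_MIN, EORTC_RANK_MAX = 1, 4

SQ_MIN, SQ_MAX = 6, 30
DTS_MIN, DTS_MAX = 4, 20


class CodingError(ValueError):
    """An item response outside its declared rank bounds."""


class MissingItemError(ValueError):
    """A constituent item required under the strict missing-data policy is absent."""


@dataclass(frozen=True)
class ItemDescriptor:
    item_id: int
    polarity: str  # "positive" | "negative"
    wording: str = ""


@dataclass(frozen=True)
class ItemBank:
    """Static description of the MOS-SS item structure used for scoring."""

    items: tuple[ItemDescriptor, ...] = field(default_factory=lambda: _default_items())
    sq_items: tuple[int, ...] = SQ_ITEMS
    dts_items: tuple[int, ...] = DTS_ITEMS
    reversed_ids: frozenset[int] = REVERSED_ITEMS
    rank_min: int = MOS_RANK_MIN
    rank_max: int = MOS_RANK_MAX

    def __post_init__(self) -> None:
        if set(self.sq_items) & set(self.dts_items):
            raise ValueError("SQ and DTS item sets overlap")
        if set(self.sq_items) | set(self.dts_items) != set(range(3, 13)):
            raise ValueError("SQ and DTS items must partition items 3..12")
        neg = {d.item_id for d in self.items if d.polarity == "negative" and d.item_id >= 3}
        if neg != set(self.reversed_ids):
            raise ValueError("reversed_ids must equal the negative-polarity scored items")


def _default_items() -> tuple[ItemDescriptor, ...]:
    wordings = {
        1: "time to fall asleep",
        2: "hours of sleep per night",
        3: "sleep was not quiet",
        4: "enough sleep to feel rested",
        5: "awaken short of breath or with headache",
        6: "drowsy or sleepy during the day",
        7: "trouble falling asleep",
        8: "awaken and trouble falling asleep again",
        9: "trouble staying awake during the day",
        10: "snoring",
        11: "daytime naps",
        12: "got the amount of sleep needed",
    }
    out = []
    for i in range(1, 13):
        pol = "positive" if i in POSITIVE_ITEMS else "negative"
        out.append(ItemDescriptor(i, pol, wordings[i]))
    return tuple(out)


DEFAULT_ITEM_BANK = ItemBank()


def reverse_rank(r: int, item_id: int | None = None) -> int:
    """Reverse a 5-category frequency rank (``6 - r``); an involution on 1..5."""
    if not (MOS_RANK_MIN <= r <= MOS_RANK_MAX) or int(r) != r:
        where = f" for item {item_id}" if item_id is not None else ""
        raise CodingError(f"rank {r!r}{where} outside {MOS_RANK_MIN}..{MOS_RANK_MAX}")
    return 6 - int(r)


def _get_items(
    responses: Mapping[int, object], item_ids: Sequence[int], policy: str
) -> Optional[dict[int, int]]:
    """Validate and collect the requested MOS item ranks.

    Returns None when items are missing and *policy* is lenient; raises
    under strict policy.  Missing = absent key, None, or NaN.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    out: dict[int, int] = {}
    for i in item_ids:
        v = responses.get(i)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            if policy == "strict":
                return None
            continue
        vi = int(v)
        if vi != v or not (MOS_RANK_MIN <= vi <= MOS_RANK_MAX):
            raise CodingError(f"rank {v!r} for item {i} outside {MOS_RANK_MIN}..{MOS_RANK_MAX}")
        out[i] = vi
    return out


def score_sq(mos: Mapping[int, object], policy: str = "strict") -> float:
    """Sleep-quality score: raw items 4 and 12 plus reversed 3, 5, 7, 8.

    Under the default strict policy the score is undefined (NaN) when
    any of the six constituents is missing; under the lenient half-rule
    the available oriented items are prorated to the six-item sum when
    at least half are present.
    """
    return _sum_score(mos, SQ_ITEMS, policy)


def score_dts(mos: Mapping[int, object], policy: str = "strict") -> float:
    """Daytime-sleepiness score: sum of reversed items 6, 9, 10, 11."""
    return _sum_score(mos, DTS_ITEMS, policy)


def _sum_score(mos: Mapping[int, object], item_ids: Sequence[int], policy: str) -> float:
    got = _get_items(mos, item_ids, policy)
    if got is None:
        return float("nan")
    oriented = [reverse_rank(v, i) if i in REVERSED_ITEMS else v for i, v in got.items()]
    k = len(oriented)
    if k == len(item_ids):
        return float(sum(oriented))
    if 2 * k < len(item_ids) or k == 0:
        return float("nan")
    # lenient half-rule: prorate the mean of available items to the full sum
    return float(sum(oriented) / k * len(item_ids))


def score_slp9(
    mos: Mapping[int, object],
    policy: str = "strict",
    items: Sequence[int] = SLP9_ITEMS,
) -> float:
    """MOS Sleep Problems Index II: mean of 0-100 problem-oriented items.

    Each constituent rank is linearly rescaled to 0-100 with the problem
    direction up: reversed items contribute ``(5 - r) / 4 * 100``, items
    1, 4 and 12 (already worst-high) contribute ``(r - 1) / 4 * 100``.
    Higher values mean more sleep problems.
    """
    got = _get_items(mos, items, policy)
    if got is None:
        return float("nan")
    vals = []
    for i, v in got.items():
        if i in REVERSED_ITEMS:
            vals.append((MOS_RANK_MAX - v) / (MOS_RANK_MAX - MOS_RANK_MIN) * 100.0)
        else:
            vals.append((v - MOS_RANK_MIN) / (MOS_RANK_MAX - MOS_RANK_MIN) * 100.0)
    k = len(vals)
    if policy == "strict" and k < len(items):
        return float("nan")
    if k == 0 or 2 * k < len(items):
        return float("nan")
    return float(np.mean(vals))


def classify(
    sq: float,
    dts: float,
    cutoff_sq: int = DEFAULT_SQ_CUTOFF,
    cutoff_dts: int = DEFAULT_DTS_CUTOFF,
) -> tuple[bool, bool]:
    """Apply the screening cut-offs: flags are ``sq >= cutoff_sq``, ``dts >= cutoff_dts``.

    NaN scores yield False flags (no evidence of disruption is not the
    same as evidence of none; callers should inspect the scores).
    """
    sq_flag = bool(not _isnan(sq) and sq >= cutoff_sq)
    dts_flag = bool(not _isnan(dts) and dts >= cutoff_dts)
    return sq_flag, dts_flag


def _isnan(x: float) -> bool:
    try:
        return math.isnan(x)
    except TypeError:
        return False


@dataclass(frozen=True)
class ScoreResult:
    """SQ, DTS and SLP9 scores with cut-off classifications for one record."""

    sq: float
    dts: float
    slp9: float
    sq_flag: bool
    dts_flag: bool
    cutoff_sq: int = DEFAULT_SQ_CUTOFF
    cutoff_dts: int = DEFAULT_DTS_CUTOFF


def score_record(
    mos: Mapping[int, object],
    policy: str = "strict",
    cutoff_sq: int = DEFAULT_SQ_CUTOFF,
    cutoff_dts: int = DEFAULT_DTS_CUTOFF,
) -> ScoreResult:
    sq = score_sq(mos, policy)
    dts = score_dts(mos, policy)
    slp9 = score_slp9(mos, policy)
    sq_flag, dts_flag = classify(sq, dts, cutoff_sq, cutoff_dts)
    return ScoreResult(sq, dts, slp9, sq_flag, dts_flag, cutoff_sq, cutoff_dts)


def mos_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("mos_q")]


def score_dataframe(
    df: pd.DataFrame,
    policy: str = "strict",
    cutoff_sq: int = DEFAULT_SQ_CUTOFF,
    cutoff_dts: int = DEFAULT_DTS_CUTOFF,
) -> pd.DataFrame:
    """Append sq, dts, slp9, sq_flag, dts_flag columns to a wide cohort table.

    Expects MOS item columns named ``mos_q1`` .. ``mos_q12`` with empty
    cells as NaN.  Returns a copy; the input is never modified.
    """
    out = df.copy()
    sq, dts, slp9, fsq, fdts = [], [], [], [], []
    for _, row in df.iterrows():
        mos = {
            i: row.get(f"mos_q{i}")
            for i in range(1, 13)
            if f"mos_q{i}" in df.columns
        }
        res = score_record(mos, policy, cutoff_sq, cutoff_dts)
        sq.append(res.sq)
        dts.append(res.dts)
        slp9.append(res.slp9)
        fsq.append(res.sq_flag)
        fdts.append(res.dts_flag)
    out["sq"] = sq
    out["dts"] = dts
    out["slp9"] = slp9
    out["sq_flag"] = fsq
    out["dts_flag"] = fdts
    return out
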