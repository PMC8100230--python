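"""External epidemic information and the needs it induces.

Agents never see raw news; they see four scalar *information intensities* in
[0, 1]: positive/negative signals about material supply and positive/negative
signals about environmental safety.  Global material need M(t) and safety
need S(t) follow from the net signal:

    M(t) = (1 - (I_M+ - I_M-)) / 2        S(t) = (1 - (I_S+ - I_S-)) / 2

so fully positive news drives the need to 0 and fully negative news drives it
to 1.  Needs are global: the intensities come from public media and every
agent reads the same schedule.

Intensities themselves can be quantified from media statistics (topic reading
counts, crawled comment counts, daily death counts) as ``count / cap`` capped
at 1, where the cap is the saturation level of the platform metric.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from .network import ConfigurationError

__all__ = [
    "InformationPoint",
    "InformationSchedule",
    "TopicStats",
    "material_need",
    "safety_need",
    "schedule_at",
    "intensity_from_count",
    "average_intensity",
    "quantify_topic_stats",
]


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal round-half-up (report convention for intensity tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class InformationPoint:
    """One step's four information intensities, each in [0, 1]."""

    im_pos: float = 0.0
    im_neg: float = 0.0
    is_pos: float = 0.0
    is_neg: float = 0.0

    def __post_init__(self):
        for name in ("im_pos", "im_neg", "is_pos", "is_neg"):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))


def material_need(point: InformationPoint) -> float:
    """Global material need M(t) in [0, 1] induced by ``point``."""
    return (1.0 - (point.im_pos - point.im_neg)) / 2.0


def safety_need(point: InformationPoint) -> float:
    """Global safety need S(t) in [0, 1] induced by ``point``."""
    return (1.0 - (point.is_pos - point.is_neg)) / 2.0


@dataclass(frozen=True)
class InformationSchedule:
    """Piecewise-constant information signal over discrete time steps.

    ``segments`` is an ordered tuple of ``(start_step, InformationPoint)``;
    start steps are strictly increasing and the first one must be 0 so that
    every step has a defined signal.
    """

    segments: tuple[tuple[int, InformationPoint], ...]

    def __post_init__(self):
        if not self.segments:
            raise ConfigurationError("schedule needs at least one segment")
        starts = [int(s) for s, _ in self.segments]
        if starts[0] != 0:
            raise ConfigurationError("first segment must start at step 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError("segment start steps must strictly increase")
        object.__setattr__(
            self,
            "segments",
            tuple((int(s), p) for s, p in self.segments),
        )

    @classmethod
    def constant(cls, point: InformationPoint) -> "InformationSchedule":
        return cls(((0, point),))

    @classmethod
    def from_dicts(cls, rows: Iterable[dict]) -> "InformationSchedule":
        segs = tuple(
            (
                int(r["start_step"]),
                InformationPoint(
                    im_pos=r.get("im_pos", 0.0),
                    im_neg=r.get("im_neg", 0.0),
                    is_pos=r.get("is_pos", 0.0),
                    is_neg=r.get("is_neg", 0.0),
                ),
            )
            for r in rows
        )
        return cls(segs)

    def at(self, t: int) -> InformationPoint:
        """Point of the last segment whose start step is <= ``t``."""
        if t < 0:
            raise ValueError("time step must be nonnegative")
        starts = [s for s, _ in self.segments]
        idx = bisect_right(starts, int(t)) - 1
        return self.segments[idx][1]


def schedule_at(schedule: InformationSchedule, t: int) -> InformationPoint:
    """Functional alias for :meth:`InformationSchedule.at`."""
    return schedule.at(t)


def intensity_from_count(count: float, cap: float, decimals: int | None = 3) -> float:
    """Information intensity ``min(count / cap, 1)`` from a media statistic.

    ``cap`` is the saturation benchmark (e.g. the highest observed topic
    reading count); any count at or above it scores 1.  ``decimals`` applies
    report rounding (half-up); pass ``None`` for the raw ratio.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    value = min(float(count) / float(cap), 1.0)
    return value if decimals is None else round_half_up(value, decimals)


def average_intensity(i1: float, i2: float, decimals: int | None = 3) -> float:
    """Mean of two (unrounded) component intensities, report-rounded."""
    _check_unit("i1", i1)
    _check_unit("i2", i2)
    value = (float(i1) + float(i2)) / 2.0
    return value if decimals is None else round_half_up(value, decimals)


@dataclass(frozen=True)
class TopicStats:
    """Media statistics for one news topic: counts plus saturation caps."""

    reading_count: float
    reading_cap: float
    comment_count: float
    comment_cap: float

    def __post_init__(self):
        if self.reading_cap <= 0 or self.comment_cap <= 0:
            raise ValueError("caps must be positive")
        if self.reading_count < 0 or self.comment_count < 0:
            raise ValueError("counts must be nonnegative")

    def intensities(self, decimals: int | None = 3) -> tuple[float, float, float]:
        """(reading-based, comment-based, averaged) intensity triple."""
        raw1 = intensity_from_count(self.reading_count, self.reading_cap, None)
        raw2 = intensity_from_count(self.comment_count, self.comment_cap, None)
        avg = average_intensity(raw1, raw2, decimals)
        if decimals is not None:
            raw1 = round_half_up(raw1, decimals)
            raw2 = round_half_up(raw2, decimals)
        return raw1, raw2, avg


def quantify_topic_stats(
    stats: pd.DataFrame | str | Path, decimals: int = 3
) -> pd.DataFrame:
    """Intensity table from a topic-statistics table.

    Input columns: ``topic, category, polarity, reading_count, reading_cap,
    comment_count, comment_cap`` (a CSV path is accepted).  Output mirrors the
    input rows with three extra columns: ``intensity_reading``,
    ``intensity_comment`` and ``intensity_average`` (the averaged value uses
    the unrounded components).
    """
    if not isinstance(stats, pd.DataFrame):
        stats = pd.read_csv(stats)
    required = {
        "topic",
        "category",
        "polarity",
        "reading_count",
        "reading_cap",
        "comment_count",
        "comment_cap",
    }
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    out = stats.copy()
    triples = [
        TopicStats(
            row.reading_count, row.reading_cap, row.comment_count, row.comment_cap
        ).intensities(decimals)
        for row in stats.itertuples()
    ]
    out["intensity_reading"] = [t[0] for t in triples]
    out["intensity_comment"] = [t[1] for t in triples]
    out["intensity_average"] = [t[2] for t in triples]
    return out
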