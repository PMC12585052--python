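"""Dated biogeographic events and sliding-window per-lineage rates.

Given a single range assigned to every node of a chronogram, a
*transition* is a branch whose parent-node and child-node ranges differ
(any set inequality, including pure expansions like {D} -> {D,E}); it is
dated at the branch midpoint.  An *origination* is a branching event,
dated exactly at the node's age, and flagged in-situ when the node and
both daughters carry the same range.

Rates are events per lineage ("per branch") per Myr: events in a
fixed-width window divided by the number of lineages extant at the
window's old edge and by the window width.  The default window width of
0.1 Myr and the 0.2-Myr triangular cones for plotted series follow the
sliding-window design this pipeline reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .treedata import Chronogram, TreeError

logger = logging.getLogger(__name__)

Kind = Literal["transition", "origination"]

DEFAULT_WINDOW = 0.1  # Myr, i.e. 100,000 years
DEFAULT_CONE = 0.2  # Myr, twice the window width


class AssignmentError(ValueError):
    """Range assignment does not cover the chronogram."""


@dataclass(frozen=True)
class EventRecord:
    """One dated biogeographic event.

    ``node`` is the child node of the branch for transitions and the
    splitting node itself for originations.
    """

    kind: Kind
    time: float
    node: int
    from_range: frozenset | None = None
    to_range: frozenset | None = None
    region: frozenset | None = None
    in_situ: bool | None = None


@dataclass(frozen=True)
class RateSeries:
    """Windowed per-lineage event rates, old windows first.

    ``old_edges`` are the window start ages (decreasing); ``values`` are
    events per lineage per Myr; ``lineages`` and ``counts`` retain the
    normalizers and raw tallies so conservation can be checked exactly:
    sum(values * width * lineages) == counts.sum().
    """

    kind: Kind
    width: float
    old_edges: np.ndarray
    values: np.ndarray
    lineages: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be > 0")
        if np.any(self.values < 0):
            raise ValueError("rates must be >= 0")

    def total_events(self) -> float:
        return float(np.sum(self.values * self.width * self.lineages))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_old_edge_mya": self.old_edges,
                "rate": self.values,
                "lineages": self.lineages,
                "events": self.counts,
            }
        )


def check_assignment(chron: Chronogram, assign: Mapping[int, frozenset]) -> None:
    for v in range(chron.n_nodes):
        if v not in assign:
            raise AssignmentError(f"no range assigned to node {v}")
        if not assign[v]:
            raise AssignmentError(f"empty range assigned to node {v}")


def extract_events(
    chron: Chronogram,
    assign: Mapping[int, frozenset],
    transition_dating: Literal["midpoint", "child"] = "midpoint",
) -> list[EventRecord]:
    """All transition and origination events implied by a node->range map.

    Transitions are dated at the branch midpoint by default (unbiased
    under a uniform change-time prior); pass ``transition_dating="child"``
    to date them at the younger node instead.  Events are returned sorted
    old to young, ties broken by node id.
    """
    check_assignment(chron, assign)
    events: list[EventRecord] = []
    for v in range(chron.n_nodes):
        p = int(chron.parent[v])
        if p >= 0 and assign[p] != assign[v]:
            if transition_dating == "midpoint":
                t = 0.5 * (float(chron.ages[p]) + float(chron.ages[v]))
            else:
                t = float(chron.ages[v])
            events.append(
                EventRecord(
                    kind="transition",
                    time=t,
                    node=v,
                    from_range=frozenset(assign[p]),
                    to_range=frozenset(assign[v]),
                )
            )
        kids = chron.children[v]
        if kids:
            in_situ = all(assign[c] == assign[v] for c in kids)
            events.append(
                EventRecord(
                    kind="origination",
                    time=float(chron.ages[v]),
                    node=v,
                    region=frozenset(assign[v]),
                    in_situ=in_situ,
                )
            )
    events.sort(key=lambda e: (-e.time, e.node, e.kind))
    return events


def sliding_window_rates(
    events: Iterable[EventRecord],
    chron: Chronogram,
    kind: Kind,
    width: float = DEFAULT_WINDOW,
    t_max: float | None = None,
    t_min: float = 0.0,
) -> RateSeries:
    """Contiguous-window per-lineage event rates from ``t_max`` to ``t_min``.

    Windows are half-open on the young side, ``[t_old, t_old - width)``,
    and share exact float boundaries so no event is double counted.  The
    normalizer is the lineage count at the window's old edge.  A window
    whose old edge carries zero lineages keeps rate 0 when it contains no
    events, and is dropped with a logged warning when it does (this can
    only happen at the root age, e.g. for the root origination).
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    if t_max is None:
        t_max = chron.root_age
    if t_max > chron.root_age + 1e-9:
        raise TreeError(f"t_max={t_max} exceeds root age {chron.root_age}")
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    times = np.array([e.time for e in events if e.kind == kind])
    m = int(np.ceil((t_max - t_min) / width - 1e-9))
    bounds = t_max - width * np.arange(m + 1)
    old_edges = bounds[:-1]
    young_edges = bounds[1:]
    if times.size:
        counts = np.array(
            [np.sum((old >= times) & (times > young)) for old, young in zip(old_edges, young_edges)],
            dtype=float,
        )
    else:
        counts = np.zeros(m)
    lineages = np.array([chron.lineages_at(min(t, chron.root_age)) for t in old_edges], dtype=float)
    keep = (lineages > 0) | (counts == 0)
    dropped = np.flatnonzero(~keep)
    for i in dropped:
        logger.warning(
            "dropping window with old edge %.6g Myr: %d event(s) but zero lineages",
            old_edges[i],
            int(counts[i]),
        )
    old_edges, young = old_edges[keep], young_edges[keep]
    counts, lineages = counts[keep], lineages[keep]
    values = np.where(lineages > 0, counts / np.maximum(lineages, 1.0) / width, 0.0)
    return RateSeries(
        kind=kind,
        width=width,
        old_edges=old_edges,
        values=values,
        lineages=lineages,
        counts=counts,
    )


def period_mean_rate(
    series: RateSeries,
    t_old: float,
    t_young: float,
    pooled: bool = False,
) -> float:
    """Average rate over the windows whose old edges lie in (t_young, t_old].

    By default the arithmetic mean of window values; with ``pooled=True``
    the alternative pooled estimator total events / total lineage-time.
    """
    eps = 1e-9
    sel = (series.old_edges > t_young + eps) & (series.old_edges <= t_old + eps)
    if not np.any(sel):
        raise ValueError(f"no windows with old edges in ({t_young}, {t_old}]")
    if pooled:
        exposure = float(np.sum(series.lineages[sel]) * series.width)
        if exposure <= 0:
            raise ValueError("zero lineage-time in the selected period")
        return float(np.sum(series.counts[sel]) / exposure)
    return float(series.values[sel].mean())


def cone_series(
    events: Iterable[EventRecord],
    chron: Chronogram,
    kind: Kind,
    cone_width: float = DEFAULT_CONE,
    grid_step: float = 0.01,
    t_max: float | None = None,
    t_min: float = 0.0,
) -> pd.DataFrame:
    """Plotted rate series: one triangular kernel per event.

    Each event at time t with N extant lineages contributes a symmetric
    triangle of total base width ``cone_width`` centred at t whose area
    is 1/N, i.e. peak height 2 / (N * cone_width).  The returned frame
    has columns ``age_mya`` (descending) and ``rate``; the series
    integrates to the sum of 1/N over events.
    """
    if cone_width <= 0:
        raise ValueError("cone width must be > 0")
    if t_max is None:
        t_max = chron.root_age
    grid = np.arange(t_max, t_min - grid_step / 2, -grid_step)
    values = np.zeros_like(grid)
    half = cone_width / 2.0
    for e in events:
        if e.kind != kind:
            continue
        n = chron.lineages_at(min(e.time, chron.root_age))
        if n == 0:
            logger.warning("skipping cone for event at %.6g Myr: zero lineages", e.time)
            continue
        peak = 2.0 / (n * cone_width)
        contrib = peak * np.clip(1.0 - np.abs(grid - e.time) / half, 0.0, None)
        values += contrib
    return pd.DataFrame({"age_mya": grid, "rate": values})


@dataclass(frozen=True)
class LTTCurve:
    """Right-continuous lineage-through-time step function.

    ``breaks`` are node ages in decreasing order starting at the clade
    origin; on the age interval [breaks[i+1], breaks[i]) the curve takes
    ``counts[i]`` lineages (2 just younger than the clade root, ending
    at the clade's tip count at the present or the truncation age).
    """

    breaks: np.ndarray  # length m+1, decreasing; last entry = young cutoff
    counts: np.ndarray  # length m

    def value(self, t: float) -> int:
        if t >= self.breaks[0] or t < self.breaks[-1] - 1e-12:
            raise ValueError(f"age {t} outside the curve span")
        # value at an exact node age belongs to the older interval
        idx = int(np.searchsorted(-self.breaks, -t, side="left")) - 1
        idx = max(idx, 0)
        return int(self.counts[min(idx, len(self.counts) - 1)])

    def truncate(self, min_age: float) -> "LTTCurve":
        breaks = np.append(self.breaks[self.breaks > min_age], min_age)
        return LTTCurve(breaks, self.counts[: len(breaks) - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_mya": self.breaks[:-1], "lineages": self.counts})


def ltt_curve(
    chron: Chronogram,
    mrca_of: Sequence[str] | None = None,
    min_age: float = 0.0,
) -> LTTCurve:
    """Lineage-through-time curve for the whole tree or a named clade.

    ``mrca_of`` restricts the curve to the clade subtended by the MRCA of
    the listed tips (at least two).  ``min_age`` truncates the young end.
    """
    if mrca_of is None:
        clade_root = chron.root
    else:
        clade_root = chron.mrca(list(mrca_of))
    nodes = chron.clade_nodes(clade_root)
    internal_ages = sorted(
        (float(chron.ages[v]) for v in nodes if not chron.is_tip(v)), reverse=True
    )
    breaks = [a for a in internal_ages if a > min_age]
    counts = np.arange(2, 2 + len(breaks))
    return LTTCurve(np.append(breaks, min_age), counts)


def events_frame(events: Iterable[EventRecord], fmt=None) -> pd.DataFrame:
    """Tabular event list (kind, time_mya, node, from, to, region, in_situ)."""
    join = fmt.format_range if fmt is not None else lambda s: "|".join(sorted(s))
    rows = []
    for e in events:
        rows.append(
            (
                e.kind,
                e.time,
                e.node,
                join(e.from_range) if e.from_range else "",
                join(e.to_range) if e.to_range else "",
                join(e.region) if e.region else "",
                "" if e.in_situ is None else str(e.in_situ).lower(),
            )
        )
    return pd.DataFrame(
        rows, columns=["kind", "time_mya", "node", "from", "to", "region", "in_situ"]
    )
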