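"""Data model and CSV I/O for staged-removal immigration experiments.

A removal experiment depletes a site of territorial residents by a constant
number of individuals per event and censuses untagged arrivals (immigrants)
between events.  Each :class:`RemovalEvent` records one removal/census cycle:
how many fish were taken, how many remained immediately afterwards (the
density ``D_t``), and how many immigrants arrived before the next count
(``I_t``).  Immigrants join the local population and are themselves eligible
for removal at later events, which gives every consecutive pair of events the
bookkeeping identity::

    next.n_remaining == this.n_remaining + this.n_immigrants - next.n_removed

Event index 0 is reserved for pre-removal census visits (no catch, and no
immigration, since sites start saturated); several index-0 rows per site are
allowed.  Rows with ``n_removed == 0`` at a positive index represent
post-extinction observations with nothing left to catch.

The on-disk format is a plain UTF-8 CSV with header
``site,event,removed,remaining,immigrants``.  The initial abundance of a site
is either supplied through a JSON sidecar mapping site id to ``n_initial`` or
inferred as ``remaining + removed`` of the first row (exact, because no
immigrant can arrive before the first census).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "RemovalEvent",
    "SiteSeries",
    "StudyDataset",
    "FormatError",
    "ValidationError",
    "read_events",
    "write_events",
    "COLUMNS",
]

COLUMNS = ("site", "event", "removed", "remaining", "immigrants")


class FormatError(ValueError):
    """The input table does not have the expected structure."""


class ValidationError(ValueError):
    """The table is well formed but internally inconsistent."""


def _as_count(value, what: str) -> int:
    """Coerce to a non-negative integer, rejecting fractional input."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{what} must be a number, got {value!r}") from None
    if f != int(f):
        raise ValidationError(f"{what} must be an integer, got {value!r}")
    i = int(f)
    if i < 0:
        raise ValidationError(f"{what} must be non-negative, got {i}")
    return i


@dataclass(frozen=True)
class RemovalEvent:
    """One removal/census cycle.

    Parameters
    ----------
    event_index : int
        Ordinal of the event; 0 marks a pre-removal observation.
    n_removed : int
        Fish removed at this event; equals the number of new vacancies.
    n_remaining : int
        Fish present immediately after the removal (density ``D_t``).
    n_immigrants : int
        Untagged arrivals between this removal and the next count (``I_t``).
    """

    event_index: int
    n_removed: int
    n_remaining: int
    n_immigrants: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_index", _as_count(self.event_index, "event_index"))
        object.__setattr__(self, "n_removed", _as_count(self.n_removed, "n_removed"))
        object.__setattr__(self, "n_remaining", _as_count(self.n_remaining, "n_remaining"))
        object.__setattr__(self, "n_immigrants", _as_count(self.n_immigrants, "n_immigrants"))


@dataclass
class SiteSeries:
    """Ordered removal events for one site plus its initial abundance."""

    site_id: str
    n_initial: int
    events: list[RemovalEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = list(self.events)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.n_initial <= 0:
            raise ValidationError(f"site {self.site_id}: n_initial must be positive")
        indices = [e.event_index for e in self.events]
        n_pre = sum(1 for i in indices if i == 0)
        if any(i == 0 for i in indices[n_pre:]):
            raise ValidationError(
                f"site {self.site_id}: pre-removal (index 0) rows must precede removal events"
            )
        positive = indices[n_pre:]
        if positive != list(range(1, len(positive) + 1)):
            raise ValidationError(
                f"site {self.site_id}: event indices must run 1..n without gaps, got {positive}"
            )
        for e in self.events[:n_pre]:
            if e.n_removed != 0:
                raise ValidationError(
                    f"site {self.site_id}: pre-removal row has n_removed={e.n_removed}"
                )
        # bookkeeping identity chained from the initial abundance
        prev_remaining, prev_immigrants = self.n_initial, 0
        for e in self.events:
            expected = prev_remaining + prev_immigrants - e.n_removed
            if e.n_remaining != expected:
                raise ValidationError(
                    f"site {self.site_id}, event {e.event_index}: n_remaining={e.n_remaining} "
                    f"but {prev_remaining} + {prev_immigrants} - {e.n_removed} = {expected}"
                )
            prev_remaining, prev_immigrants = e.n_remaining, e.n_immigrants

    # -- convenience -------------------------------------------------------
    @property
    def n_pre_observations(self) -> int:
        return sum(1 for e in self.events if e.event_index == 0)

    @property
    def total_removed(self) -> int:
        return sum(e.n_removed for e in self.events)

    @property
    def total_immigrants(self) -> int:
        return sum(e.n_immigrants for e in self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[RemovalEvent]:
        return iter(self.events)


@dataclass
class StudyDataset:
    """A collection of site series with unique site ids."""

    sites: list[SiteSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site ids: {dup}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteSeries]:
        return iter(self.sites)

    def get(self, site_id: str) -> SiteSeries:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


def _site_from_rows(site_id: str, rows: pd.DataFrame, n_initial: int | None) -> SiteSeries:
    rows = rows.sort_values("event", kind="stable")
    events = [
        RemovalEvent(
            event_index=_as_count(r.event, f"site {site_id}: event"),
            n_removed=_as_count(r.removed, f"site {site_id}: removed"),
            n_remaining=_as_count(r.remaining, f"site {site_id}: remaining"),
            n_immigrants=_as_count(r.immigrants, f"site {site_id}: immigrants"),
        )
        for r in rows.itertuples()
    ]
    if n_initial is None:
        # before the first census no immigrant has arrived, so the first row
        # satisfies remaining = n_initial - removed exactly
        first = events[0]
        n_initial = first.n_remaining + first.n_removed
    return SiteSeries(site_id=str(site_id), n_initial=n_initial, events=events)


def read_events(path: str | Path, sidecar: str | Path | Mapping[str, int] | None = None) -> StudyDataset:
    """Read an event table, validating structure and bookkeeping.

    Parameters
    ----------
    path : path-like
        CSV file with columns ``site,event,removed,remaining,immigrants``.
    sidecar : path-like, mapping, or None
        Optional source of per-site initial abundances: a JSON file or a
        mapping ``{site_id: n_initial}``.  When absent, ``n_initial`` is
        inferred from the first row of each site.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If counts are negative/fractional or the bookkeeping identity fails.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    initials: Mapping[str, int] = {}
    if sidecar is not None:
        if isinstance(sidecar, Mapping):
            initials = sidecar
        else:
            initials = json.loads(Path(sidecar).read_text())
    sites = []
    for site_id, rows in df.groupby("site", sort=False):
        n_init = initials.get(str(site_id))
        sites.append(_site_from_rows(str(site_id), rows, n_init))
    return StudyDataset(sites=sites)


def to_frame(data: StudyDataset) -> pd.DataFrame:
    """Flatten a dataset to a long-format table with the canonical columns."""
    records = [
        (s.site_id, e.event_index, e.n_removed, e.n_remaining, e.n_immigrants)
        for s in data
        for e in s
    ]
    return pd.DataFrame.from_records(records, columns=list(COLUMNS))


def write_events(data: StudyDataset, path: str | Path) -> None:
    """Write a dataset as CSV; ``read_events`` round-trips it field-for-field."""
    to_frame(data).to_csv(path, index=False)
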