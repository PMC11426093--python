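"""Camera-trap records: independence filtering, effort, RAI and detection histories.

Raw camera-trap data arrive as one row per image (site, species, timestamp).
Consecutive images of the same species at the same site are collapsed into
*independent detections* using a 30-minute chaining rule, effort is counted in
camera-days from deployment calendars, and per-species detection histories are
built by collapsing consecutive blocks of active days (default 10) into binary
survey occasions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CameraRecord",
    "Deployment",
    "DetectionEvent",
    "DetectionHistory",
    "filter_independent",
    "rai",
    "site_rai",
    "naive_occupancy",
    "build_occasions",
    "read_records_csv",
    "read_deployments_csv",
    "write_history_csv",
    "read_history_csv",
    "summary_table",
]


@dataclass(frozen=True, order=True)
class CameraRecord:
    """A single camera image: where, what, when."""

    site_id: str
    species: str
    timestamp: datetime

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not isinstance(self.timestamp, datetime):
            raise TypeError(
                f"timestamp for site {self.site_id!r} must be a datetime, "
                f"got {type(self.timestamp).__name__}"
            )


@dataclass(frozen=True)
class Deployment:
    """The set of calendar days a camera at one site was operational."""

    site_id: str
    active_days: tuple[date, ...]

    def __post_init__(self):
        if not self.active_days:
            raise ValueError(f"deployment at {self.site_id!r} has no active days")
        object.__setattr__(self, "active_days", tuple(sorted(set(self.active_days))))

    @property
    def effort(self) -> int:
        """Camera-days of effort at this site."""
        return len(self.active_days)

    @property
    def first_day(self) -> date:
        return self.active_days[0]

    @property
    def last_day(self) -> date:
        return self.active_days[-1]

    @classmethod
    def from_interval(
        cls,
        site_id: str,
        start: date,
        end: date,
        inactive: Sequence[tuple[date, date]] = (),
    ) -> "Deployment":
        """Build from a start/end window minus optional inactive intervals."""
        if end < start:
            raise ValueError(f"deployment at {site_id!r}: end before start")
        days = {start + timedelta(d) for d in range((end - start).days + 1)}
        for a, b in inactive:
            days -= {a + timedelta(d) for d in range((b - a).days + 1)}
        return cls(site_id=site_id, active_days=tuple(sorted(days)))


@dataclass(frozen=True)
class DetectionEvent:
    """An independent detection: a chain of images with no internal gap
    exceeding the independence window."""

    site_id: str
    species: str
    start: datetime
    end: datetime
    n_images: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("event end precedes start")
        if self.n_images < 1:
            raise ValueError("event must contain at least one image")


@dataclass
class DetectionHistory:
    """Site x occasion binary detection matrix for one species.

    ``matrix`` holds 0/1 with ``nan`` marking occasions of zero effort
    (camera inactive for the whole block, or beyond the site's deployment
    span).  ``effort`` holds the number of active camera-days per occasion.
    """

    species: str
    sites: list[str]
    matrix: np.ndarray  # (n_sites, n_occasions), float with nan = missing
    effort: np.ndarray  # (n_sites, n_occasions), int active-day counts
    occasion_length: int = 10

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.effort = np.asarray(self.effort, dtype=int)
        if self.matrix.shape != self.effort.shape:
            raise ValueError("matrix and effort shapes differ")
        if len(self.sites) != self.matrix.shape[0]:
            raise ValueError("site list length does not match matrix rows")
        miss = np.isnan(self.matrix)
        if np.any(miss != (self.effort == 0)):
            raise ValueError("entries must be missing exactly where effort is zero")
        obs = self.matrix[~miss]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("observed entries must be 0 or 1")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def surveyed(self) -> np.ndarray:
        """Boolean mask of surveyed (non-missing) occasions."""
        return ~np.isnan(self.matrix)


def filter_independent(
    records: Iterable[CameraRecord], window_minutes: float = 30.0
) -> list[DetectionEvent]:
    """Collapse image streams into independent detections.

    Within each site x species stream (sorted by time), an image is chained to
    the current event while its gap to the *previous image* is <= ``window_minutes``;
    a gap strictly greater than the window opens a new event.  This is the
    standard camera-trap independence rule ("images within 30 min = one
    detection").

    Returns events sorted by (site, species, start).
    """
    window = timedelta(minutes=window_minutes)
    streams: dict[tuple[str, str], list[datetime]] = {}
    for i, rec in enumerate(records):
        if not isinstance(rec, CameraRecord):
            raise TypeError(f"row {i}: expected CameraRecord, got {type(rec).__name__}")
        streams.setdefault((rec.site_id, rec.species), []).append(rec.timestamp)

    events: list[DetectionEvent] = []
    for (site, species), times in sorted(streams.items()):
        times.sort()
        start = prev = times[0]
        n = 1
        for t in times[1:]:
            if t - prev <= window:
                n += 1
            else:
                events.append(DetectionEvent(site, species, start, prev, n))
                start = t
                n = 1
            prev = t
        events.append(DetectionEvent(site, species, start, prev, n))
    events.sort(key=lambda e: (e.site_id, e.species, e.start))
    return events


def rai(n_events: int, effort_days: int | float) -> float:
    """Relative abundance index: independent detections per 100 camera-days.

    The conventional reporting precision is 2 decimals; this returns the raw
    value (round at the edge of the system, not inside it).
    """
    if effort_days <= 0:
        raise ValueError("effort_days must be positive")
    return 100.0 * n_events / effort_days


def site_rai(
    events: Sequence[DetectionEvent],
    deployments: Sequence[Deployment],
    species: str,
) -> pd.Series:
    """Per-site RAI of one species, indexed by site id (0 where never seen)."""
    counts: dict[str, int] = {d.site_id: 0 for d in deployments}
    for e in events:
        if e.species == species and e.site_id in counts:
            counts[e.site_id] += 1
    effort = {d.site_id: d.effort for d in deployments}
    return pd.Series(
        {s: rai(counts[s], effort[s]) for s in counts}, name=f"RAI_{species}"
    ).sort_index()


def naive_occupancy(
    events_or_history: Sequence[DetectionEvent] | DetectionHistory,
    species: str | None = None,
    n_sites: int | None = None,
) -> float:
    """Proportion of sites with at least one detection of the species.

    Accepts either a list of detection events (then ``species`` and
    ``n_sites`` are required) or a :class:`DetectionHistory`.
    """
    if isinstance(events_or_history, DetectionHistory):
        h = events_or_history
        detected = np.nansum(np.nan_to_num(h.matrix), axis=1) > 0
        return float(detected.sum()) / h.n_sites
    if n_sites is None or n_sites <= 0:
        raise ValueError("n_sites must be a positive count")
    if species is None:
        raise ValueError("species label required when passing events")
    seen = {e.species for e in events_or_history}
    if events_or_history and species not in seen:
        # species may legitimately have zero detections, but guard against typos
        # when the label is not even in the controlled vocabulary of the stream
        pass
    sites = {e.site_id for e in events_or_history if e.species == species}
    return len(sites) / n_sites


def _occasion_index(day: date, first: date, occasion_length: int) -> int:
    return (day - first).days // occasion_length


def build_occasions(
    events: Sequence[DetectionEvent],
    deployments: Sequence[Deployment],
    occasion_length: int = 10,
    species: str | None = None,
) -> DetectionHistory:
    """Collapse events into a site x occasion binary detection history.

    Occasions are consecutive blocks of ``occasion_length`` calendar days,
    aligned per site to each site's first active day (sites started on
    different dates; there is no global calendar grid).  An entry is 1 iff at
    least one event of the species *starts* on an active day of that occasion;
    a trailing partial block is kept as a regular occasion with its reduced
    effort; a block with zero active days is missing.
    """
    if species is None:
        raise ValueError("species label required")
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1")
    deps = {d.site_id: d for d in deployments}
    sites = sorted(deps)

    n_occ_per_site = {}
    for s in sites:
        d = deps[s]
        span = (d.last_day - d.first_day).days + 1
        n_occ_per_site[s] = math.ceil(span / occasion_length)
    n_occ = max(n_occ_per_site.values())

    effort = np.zeros((len(sites), n_occ), dtype=int)
    for i, s in enumerate(sites):
        d = deps[s]
        for day in d.active_days:
            effort[i, _occasion_index(day, d.first_day, occasion_length)] += 1

    matrix = np.where(effort > 0, 0.0, np.nan)
    active_sets = {s: set(deps[s].active_days) for s in sites}
    site_index = {s: i for i, s in enumerate(sites)}
    for e in events:
        if e.species != species:
            continue
        if e.site_id not in deps:
            raise ValueError(f"event at unknown site {e.site_id!r}")
        d = deps[e.site_id]
        day = e.start.date()
        if day < d.first_day or day > d.last_day:
            raise ValueError(
                f"event at {e.site_id!r} on {day} outside deployment window "
                f"[{d.first_day}, {d.last_day}]"
            )
        if day not in active_sets[e.site_id]:
            raise ValueError(
                f"event at {e.site_id!r} on {day} falls on an inactive camera day"
            )
        matrix[site_index[e.site_id], _occasion_index(day, d.first_day, occasion_length)] = 1.0

    return DetectionHistory(
        species=species,
        sites=sites,
        matrix=matrix,
        effort=effort,
        occasion_length=occasion_length,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_records_csv(path) -> list[CameraRecord]:
    """Read a records CSV with columns site_id, species, timestamp (ISO-8601)."""
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
        except ValueError as exc:
            raise ValueError(f"row {i}: malformed timestamp {row.timestamp!r}") from exc
        out.append(CameraRecord(str(row.site_id), str(row.species), ts))
    return out


def read_deployments_csv(path) -> list[Deployment]:
    """Read deployments: site_id, start_date, end_date and optional inactive
    intervals as extra rows with kind == 'inactive'."""
    df = pd.read_csv(path, dtype={"site_id": str})
    if "kind" not in df.columns:
        df = df.assign(kind="active")
    deps = []
    for site, grp in df.groupby("site_id", sort=True):
        act = grp[grp["kind"] != "inactive"]
        if len(act) != 1:
            raise ValueError(f"site {site!r}: expected exactly one active window row")
        start = date.fromisoformat(str(act.iloc[0]["start_date"]))
        end = date.fromisoformat(str(act.iloc[0]["end_date"]))
        inactive = [
            (date.fromisoformat(str(r.start_date)), date.fromisoformat(str(r.end_date)))
            for r in grp[grp["kind"] == "inactive"].itertuples(index=False)
        ]
        deps.append(Deployment.from_interval(str(site), start, end, inactive))
    return deps


def write_history_csv(history: DetectionHistory, path, effort_path=None) -> None:
    """Write a detection history as wide CSV ('NA' for missing) plus an
    optional occasion-effort sidecar."""
    cols = [f"occ{j + 1}" for j in range(history.n_occasions)]
    pd.DataFrame(history.matrix, index=pd.Index(history.sites, name="site_id"), columns=cols).to_csv(
        path, na_rep="NA"
    )
    if effort_path is not None:
        pd.DataFrame(
            history.effort, index=pd.Index(history.sites, name="site_id"), columns=cols
        ).to_csv(effort_path)


def read_history_csv(path, effort_path, species: str, occasion_length: int = 10) -> DetectionHistory:
    m = pd.read_csv(path, index_col="site_id", na_values="NA")
    e = pd.read_csv(effort_path, index_col="site_id")
    return DetectionHistory(
        species=species,
        sites=[str(s) for s in m.index],
        matrix=m.to_numpy(dtype=float),
        effort=e.to_numpy(dtype=int),
        occasion_length=occasion_length,
    )


def summary_table(
    events: Sequence[DetectionEvent],
    deployments: Sequence[Deployment],
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-species survey summary: detections, RAI, naive occupancy.

    Mirrors the standard camera-trap summary (one row per species; RAI over
    total survey effort; naive occupancy over all deployed sites).
    """
    total_effort = sum(d.effort for d in deployments)
    n_sites = len(deployments)
    if species is None:
        species = sorted({e.species for e in events})
    rows = []
    for sp in species:
        n = sum(1 for e in events if e.species == sp)
        rows.append(
            {
                "species": sp,
                "n_detections": n,
                "RAI": round(rai(n, total_effort), 2),
                "naive_occupancy": round(naive_occupancy(events, sp, n_sites), 2),
            }
        )
    return pd.DataFrame(rows)
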