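"""Photo-identification catalogue: readers/writers, quality filtering, and
delineation of groups and social units from co-identification records.

The social terminology follows the sperm-whale literature: a *group* is a
short-term (hours to days) aggregation of individuals photographed on the
same day and behaving in a coordinated way; a *social unit* is a stable set
of individuals documented associating (photographed within a time window of
each other) in at least two different calendar years.
"""

from __future__ import annotations

import datetime as dt
import itertools
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import ASSOCIATION_WINDOW_HOURS, ISLAND_GAZETTEER


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotoRecord:
    """One fluke photograph of one individual.

    ``time_of_day`` is seconds since midnight (may be missing for archival
    records); ``quality`` is the 1-5 photo-quality rating Q.
    """

    individual_id: str
    date: dt.date
    time_of_day: float | None
    lat: float
    lon: float
    quality: int
    island: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.quality) <= 5:
            raise ValueError(
                f"photo of {self.individual_id} on {self.date}: "
                f"quality {self.quality} outside 1-5"
            )
        if not (abs(self.lat) <= 90 and abs(self.lon) <= 180):
            raise ValueError(
                f"photo of {self.individual_id} on {self.date}: "
                f"coordinates ({self.lat}, {self.lon}) out of range"
            )


@dataclass(frozen=True)
class GpsFix:
    timestamp: dt.datetime
    lat: float
    lon: float


@dataclass(frozen=True)
class Association:
    """An unordered pair of individuals photographed close in time.

    ``min_gap_hours`` is the minimum pairwise gap between the two
    individuals' photo times that day; ``None`` marks the same-date fallback
    used when one of the individuals has no timed photograph.
    """

    id_a: str
    id_b: str
    date: dt.date
    min_gap_hours: float | None = None

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("association ids must satisfy id_a < id_b")

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class Group:
    group_id: str
    member_ids: frozenset[str]
    observation_dates: frozenset[dt.date]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"group {self.group_id} has an empty member set")


@dataclass(frozen=True)
class SocialUnit:
    unit_id: str
    member_ids: frozenset[str]
    qualifying_year_pairs: frozenset[tuple[int, int]]


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def filter_photo_quality(
    records: Sequence[PhotoRecord], q_min: int
) -> list[PhotoRecord]:
    """Keep photographs of quality ``>= q_min`` (order preserved).

    The standard analysis threshold is Q >= 3.
    """
    if not 1 <= q_min <= 5:
        raise ValueError(f"q_min {q_min} outside 1-5")
    for i, r in enumerate(records):
        if not 1 <= int(r.quality) <= 5:
            raise ValueError(f"record {i}: quality {r.quality} outside 1-5")
    return [r for r in records if r.quality >= q_min]


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def associations(
    records: Sequence[PhotoRecord],
    window_hours: float = ASSOCIATION_WINDOW_HOURS,
) -> list[Association]:
    """Pairs of distinct individuals photographed within ``window_hours`` of
    each other on the same day.

    The gap between two individuals on a day is the minimum over all pairs
    of their photo times that day. If either individual has no timed photo
    on that day, same-date co-occurrence suffices and the association is
    flagged (``min_gap_hours is None``).
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    by_date: dict[dt.date, dict[str, list[float | None]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in records:
        by_date[r.date][r.individual_id].append(r.time_of_day)

    out: list[Association] = []
    for date in sorted(by_date):
        per_ind = by_date[date]
        for a, b in itertools.combinations(sorted(per_ind), 2):
            ta = [t for t in per_ind[a] if t is not None]
            tb = [t for t in per_ind[b] if t is not None]
            if not ta or not tb:
                out.append(Association(a, b, date, None))
                continue
            gap_h = min(abs(x - y) for x in ta for y in tb) / 3600.0
            if gap_h <= window_hours:
                out.append(Association(a, b, date, gap_h))
    return out


# ---------------------------------------------------------------------------
# Groups and social units
# ---------------------------------------------------------------------------

def _component_groups(graph: nx.Graph) -> list[frozenset[str]]:
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: sorted(c))


def delineate_groups(
    assocs: Sequence[Association], records: Sequence[PhotoRecord]
) -> list[Group]:
    """Connected components of the association graph, merged across days.

    Per day, associated individuals form day-components; day-components
    sharing at least one member are merged across days (equivalently:
    connected components of the union graph over all days, with singleton
    nodes for individuals never associated).
    """
    graph = nx.Graph()
    dates_of: dict[str, set[dt.date]] = defaultdict(set)
    for r in records:
        graph.add_node(r.individual_id)
        dates_of[r.individual_id].add(r.date)
    for a in assocs:
        graph.add_edge(a.id_a, a.id_b)
        dates_of[a.id_a].add(a.date)
        dates_of[a.id_b].add(a.date)

    groups = []
    for i, members in enumerate(_component_groups(graph), start=1):
        obs = frozenset().union(*(dates_of[m] for m in members))
        groups.append(Group(f"G{i:03d}", members, frozenset(obs)))
    return groups


def delineate_units(
    groups: Sequence[Group], assocs: Sequence[Association]
) -> list[SocialUnit]:
    """Social units: components of the association graph restricted to pairs
    associated in at least two distinct calendar years.

    Groups whose pairs never meet the two-year criterion remain groups only
    (they simply yield no unit).
    """
    years_of_pair: dict[tuple[str, str], set[int]] = defaultdict(set)
    for a in assocs:
        years_of_pair[(a.id_a, a.id_b)].add(a.year)

    graph = nx.Graph()
    pair_years: dict[tuple[str, str], set[int]] = {}
    for (a, b), years in years_of_pair.items():
        if len(years) >= 2:
            graph.add_edge(a, b)
            pair_years[(a, b)] = years

    units = []
    for i, members in enumerate(_component_groups(graph), start=1):
        ypairs: set[tuple[int, int]] = set()
        for (a, b), years in pair_years.items():
            if a in members:
                ypairs.update(itertools.combinations(sorted(years), 2))
        units.append(SocialUnit(f"U{i:03d}", members, frozenset(ypairs)))
    return units


# ---------------------------------------------------------------------------
# Island labels
# ---------------------------------------------------------------------------

def attach_islands(
    records: Sequence[PhotoRecord],
    gazetteer: Mapping[str, tuple[float, float]] | None = None,
) -> list[PhotoRecord]:
    """Label each record with the nearest island centroid (great circle)."""
    from .movement_spatial import great_circle_km

    gaz = dict(gazetteer or ISLAND_GAZETTEER)
    names = sorted(gaz)
    out = []
    for r in records:
        dists = [great_circle_km((r.lat, r.lon), gaz[n]) for n in names]
        out.append(replace(r, island=names[dists.index(min(dists))]))
    return out


# ---------------------------------------------------------------------------
# CSV I/O  (photos.csv = individual_id,date,time,lat,lon,quality[,island];
#           gps.csv = timestamp,lat,lon,track_id)
# ---------------------------------------------------------------------------

def _fmt_time(t: float | None) -> str:
    if t is None:
        return ""
    t = int(round(t))
    return f"{t // 3600:02d}:{(t % 3600) // 60:02d}:{t % 60:02d}"


def _parse_time(s: str) -> float | None:
    if s is None or s == "" or pd.isna(s):
        return None
    h, m, sec = s.split(":")
    return int(h) * 3600 + int(m) * 60 + float(sec)


def write_photos(records: Sequence[PhotoRecord], path) -> None:
    rows = [
        {
            "individual_id": r.individual_id,
            "date": r.date.isoformat(),
            "time": _fmt_time(r.time_of_day),
            "lat": f"{r.lat:.6f}",
            "lon": f"{r.lon:.6f}",
            "quality": r.quality,
            "island": r.island or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["individual_id", "date", "time", "lat", "lon", "quality", "island"],
    ).to_csv(path, index=False)


def read_photos(path) -> list[PhotoRecord]:
    df = pd.read_csv(path, dtype={"individual_id": str, "time": str, "island": str})
    out = []
    for i, row in df.iterrows():
        try:
            island = row.get("island")
            island = None if (pd.isna(island) or island == "") else str(island)
            out.append(
                PhotoRecord(
                    individual_id=str(row["individual_id"]),
                    date=dt.date.fromisoformat(str(row["date"])),
                    time_of_day=_parse_time(row.get("time")),
                    lat=round(float(row["lat"]), 6),
                    lon=round(float(row["lon"]), 6),
                    quality=int(row["quality"]),
                    island=island,
                )
            )
        except ValueError as exc:
            raise ValueError(f"photos row {i}: {exc}") from exc
    return out


def write_gps(tracks: Mapping[str, Sequence[GpsFix]], path) -> None:
    rows = []
    for track_id in sorted(tracks):
        for f in tracks[track_id]:
            rows.append(
                {
                    "timestamp": f.timestamp.isoformat(),
                    "lat": f"{f.lat:.6f}",
                    "lon": f"{f.lon:.6f}",
                    "track_id": track_id,
                }
            )
    pd.DataFrame(rows, columns=["timestamp", "lat", "lon", "track_id"]).to_csv(
        path, index=False
    )


def read_gps(path) -> dict[str, list[GpsFix]]:
    df = pd.read_csv(path, dtype={"track_id": str})
    tracks: dict[str, list[GpsFix]] = defaultdict(list)
    for _, row in df.iterrows():
        tracks[str(row["track_id"])].append(
            GpsFix(
                timestamp=dt.datetime.fromisoformat(str(row["timestamp"])),
                lat=round(float(row["lat"]), 6),
                lon=round(float(row["lon"]), 6),
            )
        )
    for track_id, fixes in tracks.items():
        times = [f.timestamp for f in fixes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"track {track_id}: timestamps not strictly increasing")
    return dict(tracks)


def write_groups(groups: Sequence[Group], path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "member_ids": ";".join(sorted(g.member_ids)),
            "observation_dates": ";".join(
                d.isoformat() for d in sorted(g.observation_dates)
            ),
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=["group_id", "member_ids", "observation_dates"]).to_csv(
        path, index=False
    )


def write_units(units: Sequence[SocialUnit], path) -> None:
    rows = [
        {
            "unit_id": u.unit_id,
            "member_ids": ";".join(sorted(u.member_ids)),
            "qualifying_year_pairs": ";".join(
                f"{a}-{b}" for a, b in sorted(u.qualifying_year_pairs)
            ),
        }
        for u in units
    ]
    pd.DataFrame(
        rows, columns=["unit_id", "member_ids", "qualifying_year_pairs"]
    ).to_csv(path, index=False)
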