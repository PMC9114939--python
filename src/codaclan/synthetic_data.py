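"""Synthetic study generator: clan-structured codas, island-resident unit
movement, and effort-biased survey resightings, with full ground truth.

The generator's defaults describe a study system shaped like the Eastern
Caribbean one: three vocal clans whose dominant identity coda types make up
54%, 61% and 57% of their output, daily repertoires of ~120 codas, social
units of ~7 individuals resident around one or two islands of the Lesser
Antilles arc, a diffusive daily movement scale of ~10 km/sqrt(day) with
mean reversion toward the home island, and a sailing survey running
leeward transects at four knots with a 15 km detection radius. Every output
comes with a truth manifest (true coda types, clan labels, unit memberships,
diffusion scale) so each pipeline stage can be scored against known truth.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coda_typing import Coda
from .config import CRUISE_SPEED_KMH, ISLAND_GAZETTEER
from .io_catalog import GpsFix, PhotoRecord
from .movement_spatial import SightingRecord, from_planar, to_planar


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeSpec:
    label: str
    n_clicks: int
    mean_icis: tuple[float, ...]
    sd: float = 0.01

    def __post_init__(self) -> None:
        if len(self.mean_icis) != self.n_clicks - 1:
            raise ValueError(f"type {self.label}: ICI length mismatch")


#: The synthetic coda type inventory. Identity types mirror the field's
#: canonical shapes (1+1+3, 5R, 2+1+1+1, long regular codas); 3R/7R/8R are
#: shared background types used by every clan.
TYPE_TABLE: dict[str, TypeSpec] = {
    t.label: t
    for t in [
        TypeSpec("1+1+3", 5, (0.45, 0.45, 0.15, 0.15)),
        TypeSpec("1+3", 4, (0.50, 0.18, 0.18)),
        TypeSpec("4R", 4, (0.30, 0.30, 0.30)),
        TypeSpec("2+3", 5, (0.20, 0.55, 0.20, 0.20)),
        TypeSpec("5R", 5, (0.22, 0.22, 0.22, 0.22)),
        TypeSpec("2+1+1+1", 5, (0.15, 0.40, 0.40, 0.40)),
        TypeSpec("6R", 6, (0.20, 0.20, 0.20, 0.20, 0.20)),
        TypeSpec("9R", 9, (0.12,) * 8),
        TypeSpec("10R", 10, (0.12,) * 9),
        TypeSpec("11R", 11, (0.11,) * 10),
        TypeSpec("3R", 3, (0.25, 0.25)),
        TypeSpec("7R", 7, (0.18,) * 6),
        TypeSpec("8R", 8, (0.20,) * 7),
    ]
}


@dataclass(frozen=True)
class ClanSpec:
    clan_id: str
    usage_mix: Mapping[str, float]
    identity_labels: frozenset[str]

    def __post_init__(self) -> None:
        if abs(sum(self.usage_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.clan_id}: usage mix does not sum to 1")
        unknown = set(self.usage_mix) - set(TYPE_TABLE)
        if unknown:
            raise ValueError(f"{self.clan_id}: unknown type labels {unknown}")


def default_clan_specs() -> list[ClanSpec]:
    """Three clans with dominant identity usage of 54%, 61% and 57%."""
    return [
        ClanSpec(
            "clan_A",
            {"1+1+3": 0.54, "1+3": 0.10, "4R": 0.07, "2+3": 0.06,
             "3R": 0.10, "7R": 0.07, "8R": 0.06},
            frozenset({"1+1+3", "1+3", "4R", "2+3"}),
        ),
        ClanSpec(
            "clan_B",
            {"5R": 0.35, "2+1+1+1": 0.26, "6R": 0.12,
             "3R": 0.12, "7R": 0.08, "8R": 0.07},
            frozenset({"5R", "2+1+1+1", "6R"}),
        ),
        ClanSpec(
            "clan_C",
            {"9R": 0.25, "10R": 0.20, "11R": 0.12,
             "3R": 0.18, "7R": 0.15, "8R": 0.10},
            frozenset({"9R", "10R", "11R"}),
        ),
    ]


@dataclass(frozen=True)
class MovementSpec:
    """Mean-reverting 2-D walk about a home island.

    ``sigma_d`` is the per-axis daily innovation sd in km/sqrt(day);
    ``attraction`` is the fraction of the distance to home recovered per day
    (0 gives pure diffusion); ``switching`` is the per-day probability of
    moving home to another island of the clan's island list.
    """

    clan_homes: Mapping[str, tuple[str, ...]]
    sigma_d: float = 10.0
    attraction: float = 0.3
    switching: float = 0.002
    jitter_km: float = 1.0
    cruise_speed_kmh: float = CRUISE_SPEED_KMH

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.cruise_speed_kmh <= 0:
            raise ValueError("sigma_d and cruise speed must be positive")


def default_movement_spec() -> MovementSpec:
    return MovementSpec(
        clan_homes={
            "clan_A": ("Dominica", "Guadeloupe"),
            "clan_B": ("Martinique", "St. Lucia"),
            "clan_C": ("Martinique",),
        }
    )


def pure_diffusion_spec(sigma_d: float = 10.0) -> MovementSpec:
    """Pure-Brownian preset (no residency) for calibration runs."""
    return MovementSpec(
        clan_homes={"clan_A": ("Martinique",)},
        sigma_d=sigma_d, attraction=0.0, switching=0.0, jitter_km=0.0,
    )


@dataclass(frozen=True)
class SurveySpec:
    transect_offset_km: float = -10.0     # leeward (west) shift of the arc
    detection_radius_km: float = 15.0
    daily_hours: float = 12.0
    seasons: tuple[tuple[int, int], ...] = (
        (2019, 2), (2019, 3), (2019, 4), (2020, 1), (2020, 2), (2020, 3)
    )
    detect_prob: float = 0.95
    quality_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    max_encounters_per_day: int = 4
    fix_interval_min: float = 5.0

    def __post_init__(self) -> None:
        if self.detection_radius_km <= 0:
            raise ValueError("detection radius must be positive")


# ---------------------------------------------------------------------------
# Coda generation
# ---------------------------------------------------------------------------

@dataclass
class CodaBundle:
    codas: list[Coda]
    truth: pd.DataFrame                 # coda_id, true_label, group_id, clan_id, date
    group_clan: dict[str, str]
    cell_counts: pd.DataFrame           # group_id, date, n_codas, sub_threshold


def _survey_date_pool() -> list[dt.date]:
    days = []
    d = dt.date(2019, 2, 1)
    while d <= dt.date(2019, 4, 30):
        days.append(d)
        d += dt.timedelta(days=1)
    d = dt.date(2020, 1, 1)
    while d <= dt.date(2020, 3, 31):
        days.append(d)
        d += dt.timedelta(days=1)
    return days


def gen_codas(
    clan_specs: Sequence[ClanSpec] | None = None,
    n_groups_per_clan: int = 5,
    days_per_group: int = 10,
    coda_rate: float = 120.0,
    sub_threshold_fraction: float = 0.05,
    ici_sd: float | None = None,
    leakage: float = 0.0,
    seed: int = 0,
) -> CodaBundle:
    """Clan-structured codas over (group, day) cells with known truth.

    Each cell's coda count is Poisson(``coda_rate``) floored at 25, except a
    ``sub_threshold_fraction`` of cells which are deliberately small (5-24
    codas) to exercise the repertoire-size filter. ICIs are Gaussian about
    the type means (floored at 10 ms). With ``leakage > 0`` a clan spends
    that usage mass on the other clans' identity types.
    """
    specs = list(clan_specs or default_clan_specs())
    rng = np.random.default_rng(seed)
    pool = _survey_date_pool()

    cells = []  # (clan_idx, group_id, day_index)
    for ci, spec in enumerate(specs):
        for g in range(n_groups_per_clan):
            group_id = f"{spec.clan_id}-G{g + 1:02d}"
            for day in range(days_per_group):
                cells.append((ci, group_id, day))
    if len(cells) > len(pool):
        raise ValueError(
            f"{len(cells)} (group, day) cells exceed the {len(pool)}-day survey window"
        )
    # stride groups through the calendar so every group spans both years
    cells.sort(key=lambda c: (c[2], c[0], c[1]))
    cell_dates = {cells[i][:2] + (cells[i][2],): pool[i] for i in range(len(cells))}

    other_identity = {
        s.clan_id: sorted(
            {t for o in specs if o.clan_id != s.clan_id for t in o.identity_labels}
        )
        for s in specs
    }

    codas: list[Coda] = []
    truth_rows = []
    cell_rows = []
    group_clan: dict[str, str] = {}
    next_id = 1
    for ci, group_id, day in cells:
        spec = specs[ci]
        group_clan[group_id] = spec.clan_id
        date = cell_dates[(ci, group_id, day)]
        sub = bool(rng.random() < sub_threshold_fraction)
        n = int(rng.integers(5, 25)) if sub else max(25, int(rng.poisson(coda_rate)))
        labels = list(spec.usage_mix)
        probs = np.array([spec.usage_mix[t] for t in labels], dtype=float)
        if leakage > 0 and other_identity[spec.clan_id]:
            probs = probs * (1.0 - leakage)
            extra = other_identity[spec.clan_id]
            labels = labels + extra
            probs = np.concatenate([probs, np.full(len(extra), leakage / len(extra))])
        draws = rng.choice(len(labels), size=n, p=probs / probs.sum())
        for d_idx in draws:
            t = TYPE_TABLE[labels[d_idx]]
            sd = t.sd if ici_sd is None else ici_sd
            icis = np.maximum(
                np.asarray(t.mean_icis) + rng.normal(0.0, sd, len(t.mean_icis)), 0.01
            )
            clicks = tuple(np.concatenate([[0.0], np.cumsum(icis)]))
            coda_id = f"C{next_id:06d}"
            next_id += 1
            codas.append(Coda(coda_id, "survey", date, group_id, clicks))
            truth_rows.append(
                {"coda_id": coda_id, "true_label": t.label, "group_id": group_id,
                 "clan_id": spec.clan_id, "date": date.isoformat()}
            )
        cell_rows.append(
            {"group_id": group_id, "date": date.isoformat(), "n_codas": n,
             "sub_threshold": sub}
        )
    return CodaBundle(
        codas=codas,
        truth=pd.DataFrame(truth_rows),
        group_clan=group_clan,
        cell_counts=pd.DataFrame(cell_rows),
    )


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    dates: list[dt.date]
    ind_pos: dict[str, np.ndarray]      # individual -> (n_days, 2) planar km
    unit_of: dict[str, str]
    clan_of_unit: dict[str, str]
    spec: MovementSpec

    @property
    def clan_of(self) -> dict[str, str]:
        return {i: self.clan_of_unit[u] for i, u in self.unit_of.items()}


def _island_xy(name: str) -> np.ndarray:
    lat, lon = ISLAND_GAZETTEER[name]
    x, y = to_planar(lat, lon)
    return np.array([float(x), float(y)])


def gen_tracks(
    spec: MovementSpec | None = None,
    n_units_per_clan: int = 2,
    unit_size: int = 7,
    n_days: int = 430,
    start: dt.date = dt.date(2019, 1, 15),
    seed: int = 0,
) -> TrackSet:
    """Daily unit trajectories (mean-reverting walk about the home island)
    with per-member jitter.

    With ``attraction = 0`` and ``switching = 0`` this is pure 2-D Brownian
    motion with per-axis daily sd ``sigma_d`` — the calibration preset.
    """
    spec = spec or default_movement_spec()
    rng = np.random.default_rng(seed)
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]

    ind_pos: dict[str, np.ndarray] = {}
    unit_of: dict[str, str] = {}
    clan_of_unit: dict[str, str] = {}
    for clan in sorted(spec.clan_homes):
        islands = spec.clan_homes[clan]
        for u in range(n_units_per_clan):
            unit_id = f"{clan}-U{u + 1:02d}"
            clan_of_unit[unit_id] = clan
            home = _island_xy(islands[u % len(islands)])
            pos = home + rng.normal(0.0, spec.sigma_d, 2)
            traj = np.empty((n_days, 2))
            for t in range(n_days):
                traj[t] = pos
                if spec.switching > 0 and len(islands) > 1 and rng.random() < spec.switching:
                    others = [i for i in islands if not np.allclose(_island_xy(i), home)]
                    if others:
                        home = _island_xy(others[int(rng.integers(len(others)))])
                pos = home + (1.0 - spec.attraction) * (pos - home) \
                    + rng.normal(0.0, spec.sigma_d, 2)
            for m in range(unit_size):
                ind = f"{unit_id}-I{m + 1:02d}"
                unit_of[ind] = unit_id
                jit = (rng.normal(0.0, spec.jitter_km, traj.shape)
                       if spec.jitter_km > 0 else 0.0)
                ind_pos[ind] = traj + jit
    return TrackSet(dates, ind_pos, unit_of, clan_of_unit, spec)


def _nearest_island(x: float, y: float) -> str:
    names = sorted(ISLAND_GAZETTEER)
    d = [np.hypot(*(np.array([x, y]) - _island_xy(n))) for n in names]
    return names[int(np.argmin(d))]


def sample_sightings(
    tracks: TrackSet,
    every_n_days: int = 1,
    detect: Callable[[float, float], bool] | None = None,
    label_islands: bool = False,
) -> list[SightingRecord]:
    """Direct (survey-free) sightings from true positions.

    With ``detect=None`` every individual is recorded every
    ``every_n_days`` days regardless of position (spatially uniform
    sampling); otherwise only positions for which ``detect(x, y)`` is true
    are recorded — a deliberately biased observation process.
    """
    out: list[SightingRecord] = []
    clan_of = tracks.clan_of
    for ind in sorted(tracks.ind_pos):
        traj = tracks.ind_pos[ind]
        for t in range(0, len(tracks.dates), every_n_days):
            x, y = float(traj[t, 0]), float(traj[t, 1])
            if detect is not None and not detect(x, y):
                continue
            lat, lon = from_planar(x, y)
            out.append(
                SightingRecord(
                    individual_id=ind, date=tracks.dates[t],
                    lat=float(lat), lon=float(lon),
                    island=_nearest_island(x, y) if label_islands else "n/a",
                    clan_id=clan_of[ind],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

@dataclass
class SurveyBundle:
    photos: list[PhotoRecord]
    gps: dict[str, list[GpsFix]]
    encounters: pd.DataFrame            # date, unit_id, clan_id, lat, lon
    identification_days: set[dt.date]
    sightings: list[SightingRecord]     # photo records as daily sightings


def _transect_polyline(spec: MovementSpec, offset_km: float) -> np.ndarray:
    names = sorted(
        {i for islands in spec.clan_homes.values() for i in islands},
        key=lambda n: _island_xy(n)[1],
    )
    pts = np.array([_island_xy(n) for n in names])
    pts[:, 0] += offset_km
    # extend 30 km beyond both end islands
    first = pts[0] - np.array([0.0, 30.0])
    last = pts[-1] + np.array([0.0, 30.0])
    return np.vstack([first, pts, last])


def _polyline_point(way: np.ndarray, s: float) -> np.ndarray:
    seg = np.diff(way, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = float(np.clip(s, 0.0, cum[-1]))
    k = int(np.clip(np.searchsorted(cum, s, "right") - 1, 0, len(seg) - 1))
    frac = (s - cum[k]) / seglen[k] if seglen[k] > 0 else 0.0
    return way[k] + frac * seg[k]


def gen_survey(
    tracks: TrackSet,
    spec: SurveySpec | None = None,
    seed: int = 0,
) -> SurveyBundle:
    """Simulate the sailing survey over the track set.

    The vessel runs a leeward transect polyline (the island arc shifted
    west) back and forth at cruise speed, logging a GPS fix every 5 min for
    ``daily_hours`` per survey day. A unit whose centroid comes within the
    detection radius of the day's track is encountered (at most
    ``max_encounters_per_day``, nearest first); each member is photographed
    with probability ``detect_prob``, with photo quality drawn from
    ``quality_probs``. Detection is therefore spatially biased by design.
    """
    spec = spec or SurveySpec()
    rng = np.random.default_rng(seed)
    way = _transect_polyline(tracks.spec, spec.transect_offset_km)
    seg = np.diff(way, axis=0)
    total_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    leg_km = tracks.spec.cruise_speed_kmh * spec.daily_hours
    n_fix = int(spec.daily_hours * 60 / spec.fix_interval_min)

    season_set = set(spec.seasons)
    date_index = {d: t for t, d in enumerate(tracks.dates)}
    survey_days = [d for d in tracks.dates if (d.year, d.month) in season_set]

    # unit centroids per day
    units = sorted(tracks.clan_of_unit)
    members: dict[str, list[str]] = {u: [] for u in units}
    for ind, u in tracks.unit_of.items():
        members[u].append(ind)
    unit_traj = {
        u: np.mean([tracks.ind_pos[i] for i in sorted(members[u])], axis=0)
        for u in units
    }

    photos: list[PhotoRecord] = []
    sightings: list[SightingRecord] = []
    gps: dict[str, list[GpsFix]] = {}
    enc_rows = []
    s0, direction = 0.0, 1.0
    q_vals = np.arange(1, len(spec.quality_probs) + 1)
    for day in survey_days:
        t = date_index[day]
        step = leg_km / n_fix
        fixes_xy = []
        s = s0
        for k in range(n_fix):
            fixes_xy.append(_polyline_point(way, s))
            s += direction * step
            if s >= total_len or s <= 0.0:
                direction *= -1.0
                s = float(np.clip(s, 0.0, total_len))
        s0 = s
        fixes_xy = np.array(fixes_xy)
        lat, lon = from_planar(fixes_xy[:, 0], fixes_xy[:, 1])
        start_t = dt.datetime.combine(day, dt.time(6, 0))
        gps[day.isoformat()] = [
            GpsFix(start_t + dt.timedelta(minutes=spec.fix_interval_min * k),
                   float(lat[k]), float(lon[k]))
            for k in range(n_fix)
        ]

        dists = {
            u: float(np.min(np.hypot(*(fixes_xy - unit_traj[u][t]).T)))
            for u in units
        }
        near = sorted(
            (u for u in units if dists[u] <= spec.detection_radius_km),
            key=lambda u: dists[u],
        )[: spec.max_encounters_per_day]
        for order, u in enumerate(near):
            cx, cy = unit_traj[u][t]
            elat, elon = from_planar(cx, cy)
            enc_rows.append(
                {"date": day.isoformat(), "unit_id": u,
                 "clan_id": tracks.clan_of_unit[u],
                 "lat": float(elat), "lon": float(elon)}
            )
            window_start = (8.0 + 3.5 * order) * 3600.0
            for ind in sorted(members[u]):
                if rng.random() > spec.detect_prob:
                    continue
                x, y = tracks.ind_pos[ind][t]
                plat, plon = from_planar(float(x), float(y))
                tod = window_start + rng.uniform(-1800.0, 1800.0)
                island = _nearest_island(float(x), float(y))
                q = int(rng.choice(q_vals, p=np.asarray(spec.quality_probs)))
                photos.append(
                    PhotoRecord(ind, day, tod, round(float(plat), 6),
                                round(float(plon), 6), q, island)
                )
                sightings.append(
                    SightingRecord(ind, day, float(plat), float(plon), island,
                                   tracks.clan_of_unit[u], tod)
                )
    return SurveyBundle(
        photos=photos,
        gps=gps,
        encounters=pd.DataFrame(enc_rows,
                                columns=["date", "unit_id", "clan_id", "lat", "lon"]),
        identification_days={p.date for p in photos},
        sightings=sightings,
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    codas: CodaBundle
    tracks: TrackSet
    survey: SurveyBundle
    manifest: dict


def gen_all(seed: int = 42, preset: str = "default_ec") -> Bundle:
    """Every pipeline input plus a ground-truth manifest.

    Presets: ``default_ec`` (3 clans, island residency), ``etp_like``
    (pure diffusion, no residency), ``null_no_clans`` (a single clan — no
    cultural structure to find).
    """
    if preset == "default_ec":
        clan_specs = default_clan_specs()
        mspec = default_movement_spec()
    elif preset == "etp_like":
        clan_specs = default_clan_specs()[:2]
        mspec = MovementSpec(
            clan_homes={"clan_A": ("Dominica",), "clan_B": ("Martinique",)},
            sigma_d=25.0, attraction=0.0, switching=0.0,
        )
    elif preset == "null_no_clans":
        base = default_clan_specs()[0]
        clan_specs = [base]
        mspec = MovementSpec(clan_homes={"clan_A": ("Dominica", "Martinique")})
    else:
        raise ValueError(f"unknown preset {preset!r}")

    codas = gen_codas(clan_specs, seed=seed)
    tracks = gen_tracks(
        mspec,
        n_units_per_clan=max(1, 6 // len(clan_specs)),
        seed=seed + 1,
    )
    survey = gen_survey(tracks, seed=seed + 2)
    manifest = {
        "seed": seed,
        "preset": preset,
        "group_clan": codas.group_clan,
        "unit_clan": tracks.clan_of_unit,
        "individual_unit": tracks.unit_of,
        "sigma_d": tracks.spec.sigma_d,
        "attraction": tracks.spec.attraction,
        "identity_labels": {
            s.clan_id: sorted(s.identity_labels) for s in clan_specs
        },
        "n_cells": len(codas.cell_counts),
        "n_cells_ge25": int((codas.cell_counts["n_codas"] >= 25).sum()),
    }
    return Bundle(codas, tracks, survey, manifest)


def write_bundle(bundle: Bundle, outdir) -> None:
    from .coda_typing import write_codas
    from .io_catalog import write_gps, write_photos
    from .movement_spatial import write_sightings

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_codas(bundle.codas.codas, out / "codas.csv")
    bundle.codas.truth.to_csv(out / "coda_truth.csv", index=False)
    write_photos(bundle.survey.photos, out / "photos.csv")
    write_gps(bundle.survey.gps, out / "gps.csv")
    write_sightings(bundle.survey.sightings, out / "sightings.csv")
    bundle.survey.encounters.to_csv(out / "encounters.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
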