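"""Vocal-clan delineation from daily coda usage repertoires.

A *usage repertoire* is the distribution of coda-type proportions produced
on one day (all codas recorded that day are pooled and keyed by the group or
combination of groups encountered). Clans are delineated by (1) average-
linkage clustering of repertoires on Bhattacharyya similarity, (2) searching
dendrogram cuts for the largest partition in which every cluster owns at
least one *identity coda type* — a type used consistently within one cluster
and rarely outside it — and (3) re-clustering on identity-type usage alone
as a stability check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .coda_typing import UNCLASSIFIED, Coda, TypeAssignment
from .config import IDCALL_DEFAULTS, SWEEP_GRID_DEFAULT


# ---------------------------------------------------------------------------
# Usage repertoires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UsageRepertoire:
    repertoire_id: str      # "<date>|<group label>"
    group_label: str        # group id, or "+"-joined ids when pooled
    date: object
    counts: Mapping[str, int]      # classified codas per type_id
    n_unclassified: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.counts.values()) + self.n_unclassified

    @property
    def proportions(self) -> dict[str, float]:
        tot = sum(self.counts.values())
        if tot == 0:
            return {}
        return {t: n / tot for t, n in self.counts.items()}

    def proportion(self, type_id: str) -> float:
        tot = sum(self.counts.values())
        return self.counts.get(type_id, 0) / tot if tot else 0.0


@dataclass(frozen=True)
class IdentityCodaResult:
    type_id: str
    clan_id: str
    inside_usage: float
    outside_usage: float
    inside_prevalence: float


@dataclass
class ClanAssignment:
    assignment: dict[str, str]                # repertoire_id -> clan_id
    identity_types: list[IdentityCodaResult]
    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    n_clans: int
    stability_ari: float                      # full-usage vs identity-weighted cut
    note: str = ""

    def clan_of_groups(self) -> dict[str, str | None]:
        """Propagate repertoire clans to group labels; ambiguous -> None."""
        votes: dict[str, set[str]] = {}
        for rep_id, clan in self.assignment.items():
            label = rep_id.split("|", 1)[1]
            for g in label.split("+"):
                votes.setdefault(g, set()).add(clan)
        return {g: (v.pop() if len(v) == 1 else None) for g, v in votes.items()}


def build_repertoires(
    codas: Sequence[Coda],
    assignment: Mapping[str, TypeAssignment],
    min_codas: int = 25,
) -> tuple[list[UsageRepertoire], dict]:
    """Pool all codas recorded on the same day into one repertoire.

    The repertoire is keyed by the combination of group labels recorded that
    day (a day with several groups yields a single combined repertoire).
    Unclassified codas count toward the size filter but never toward usage
    proportions. Repertoires under ``min_codas`` total codas are dropped and
    reported.
    """
    by_date: dict = {}
    for c in codas:
        day = by_date.setdefault(c.date, {"groups": set(), "codas": []})
        day["groups"].add(c.group_id)
        day["codas"].append(c)

    reps: list[UsageRepertoire] = []
    dropped: dict[str, int] = {}
    n_unclassified_total = 0
    for date in sorted(by_date):
        day = by_date[date]
        label = "+".join(sorted(day["groups"]))
        rep_id = f"{date.isoformat()}|{label}"
        counts: Counter = Counter()
        n_uncl = 0
        for c in day["codas"]:
            a = assignment.get(c.coda_id)
            if a is None or a.type_id == UNCLASSIFIED:
                n_uncl += 1
            else:
                counts[a.type_id] += 1
        n_total = sum(counts.values()) + n_uncl
        if n_total < min_codas:
            dropped[rep_id] = n_total
            continue
        n_unclassified_total += n_uncl
        reps.append(UsageRepertoire(rep_id, label, date, dict(counts), n_uncl))
    report = {
        "n_repertoires": len(reps),
        "n_dropped_repertoires": len(dropped),
        "n_codas_in_dropped": sum(dropped.values()),
        "n_unclassified_in_kept": n_unclassified_total,
        "dropped": dropped,
    }
    return reps, report


# ---------------------------------------------------------------------------
# Similarity and clustering
# ---------------------------------------------------------------------------

def repertoire_similarity(
    a: UsageRepertoire,
    b: UsageRepertoire,
    mode: str = "bhattacharyya",
    identity_types: Sequence[str] | None = None,
) -> float:
    """Bhattacharyya coefficient between two usage distributions, in [0, 1].

    ``mode="identity-weighted"`` restricts both distributions to the given
    candidate identity types and renormalizes before comparing; a repertoire
    with no mass on those types contributes similarity 0.
    """
    pa, pb = a.proportions, b.proportions
    if not pa or not pb:
        raise ValueError("zero-support repertoire")
    if mode == "bhattacharyya":
        keys = set(pa) | set(pb)
    elif mode == "identity-weighted":
        if identity_types is None:
            raise ValueError("identity-weighted mode needs identity_types")
        keys = set(identity_types)
        za = sum(pa.get(t, 0.0) for t in keys)
        zb = sum(pb.get(t, 0.0) for t in keys)
        if za == 0.0 or zb == 0.0:
            return 0.0
        pa = {t: pa.get(t, 0.0) / za for t in keys}
        pb = {t: pb.get(t, 0.0) / zb for t in keys}
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    s = sum(np.sqrt(pa.get(t, 0.0) * pb.get(t, 0.0)) for t in keys)
    return float(min(s, 1.0))


def _usage_matrix(
    repertoires: Sequence[UsageRepertoire],
) -> tuple[list[str], list[str], np.ndarray]:
    """(sorted repertoire ids, sorted type ids, proportions matrix)."""
    reps = sorted(repertoires, key=lambda r: r.repertoire_id)
    ids = [r.repertoire_id for r in reps]
    type_ids = sorted({t for r in reps for t in r.counts})
    col = {t: j for j, t in enumerate(type_ids)}
    P = np.zeros((len(reps), len(type_ids)))
    for i, r in enumerate(reps):
        for t, p in r.proportions.items():
            P[i, col[t]] = p
    return ids, type_ids, P


def similarity_matrix(
    repertoires: Sequence[UsageRepertoire],
    mode: str = "bhattacharyya",
    identity_types: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Symmetric similarity matrix over repertoires sorted by id."""
    ids, type_ids, P = _usage_matrix(repertoires)
    if np.any(P.sum(axis=1) == 0):
        raise ValueError("zero-support repertoire")
    if mode == "identity-weighted":
        if identity_types is None:
            raise ValueError("identity-weighted mode needs identity_types")
        cols = [j for j, t in enumerate(type_ids) if t in set(identity_types)]
        P = P[:, cols]
        mass = P.sum(axis=1, keepdims=True)
        nz = mass[:, 0] > 0
        P = np.divide(P, mass, out=np.zeros_like(P), where=mass > 0)
    elif mode != "bhattacharyya":
        raise ValueError(f"unknown similarity mode {mode!r}")
    R = np.sqrt(P)
    S = np.clip(R @ R.T, 0.0, 1.0)
    if mode == "identity-weighted":
        S[~nz, :] = 0.0
        S[:, ~nz] = 0.0
    np.fill_diagonal(S, 1.0)
    return ids, S


def average_linkage(S: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Average-linkage agglomeration on distance ``1 - similarity``.

    ``ids`` must be lexicographically sorted (as produced by
    :func:`similarity_matrix`) so that tie-breaking is deterministic.
    """
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(S), 1.0):
        raise ValueError("similarity matrix must have unit diagonal")
    if list(ids) != sorted(ids):
        raise ValueError("ids must be sorted for deterministic tie-breaking")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return linkage(squareform(D, checks=False), method="average")


def cut_partition(
    Z: np.ndarray, ids: Sequence[str], n_clusters: int
) -> dict[str, int]:
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return dict(zip(ids, (int(x) for x in labels)))


def to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    """Dendrogram as a newick string with branch lengths (merge heights)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(ids))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Identity coda types and clan delineation
# ---------------------------------------------------------------------------

def detect_identity_types(
    repertoires: Sequence[UsageRepertoire],
    partition: Mapping[str, object],
    u_min: float = IDCALL_DEFAULTS["u_min"],
    prevalence_min: float = IDCALL_DEFAULTS["prevalence_min"],
    out_max: float = IDCALL_DEFAULTS["out_max"],
    exclusive: bool = True,
) -> list[IdentityCodaResult]:
    """Identity coda types of each clan in ``partition``.

    Type ``t`` is an identity coda of clan ``c`` iff at least
    ``prevalence_min`` of c's repertoires use it at proportion >= ``u_min``
    and its mean proportion outside c is <= ``out_max``. With ``exclusive``
    (the default) a type meeting the thresholds for more than one clan marks
    none of them — an identity coda identifies exactly one set of
    repertoires.
    """
    ids, type_ids, P = _usage_matrix(repertoires)
    missing = [i for i in ids if i not in partition]
    if missing:
        raise ValueError(f"partition does not cover repertoires {missing[:3]}")
    labels = np.array([str(partition[i]) for i in ids])
    return _detect_from_matrix(
        P, type_ids, labels, u_min, prevalence_min, out_max, exclusive
    )


def _detect_from_matrix(
    P: np.ndarray,
    type_ids: Sequence[str],
    labels: np.ndarray,
    u_min: float,
    prevalence_min: float,
    out_max: float,
    exclusive: bool = True,
) -> list[IdentityCodaResult]:
    out: list[IdentityCodaResult] = []
    for clan in sorted(set(labels)):
        mask = labels == clan
        mean_in = P[mask].mean(axis=0)
        prevalence = (P[mask] >= u_min).mean(axis=0)
        mean_out = P[~mask].mean(axis=0) if np.any(~mask) else np.zeros(P.shape[1])
        hit = (prevalence >= prevalence_min) & (mean_out <= out_max)
        for j in np.flatnonzero(hit):
            out.append(
                IdentityCodaResult(
                    type_ids[j], str(clan),
                    float(mean_in[j]), float(mean_out[j]), float(prevalence[j]),
                )
            )
    if exclusive:
        claims = Counter(r.type_id for r in out)
        out = [r for r in out if claims[r.type_id] == 1]
    return out


def _relabel_by_size(partition: dict[str, int]) -> dict[str, str]:
    """Stable clan names: clan_1 is the largest cluster (ties by member id)."""
    sizes = Counter(partition.values())
    order = sorted(
        sizes,
        key=lambda c: (-sizes[c], min(k for k, v in partition.items() if v == c)),
    )
    name = {c: f"clan_{i}" for i, c in enumerate(order, start=1)}
    return {k: name[v] for k, v in partition.items()}


def delineate_clans(
    repertoires: Sequence[UsageRepertoire],
    u_min: float = IDCALL_DEFAULTS["u_min"],
    prevalence_min: float = IDCALL_DEFAULTS["prevalence_min"],
    out_max: float = IDCALL_DEFAULTS["out_max"],
    similarity_mode: str = "bhattacharyya",
) -> ClanAssignment:
    """Delineate vocal clans from usage repertoires.

    Procedure: cluster on full-usage similarity; over all dendrogram cuts,
    accept the one with the most clusters such that every cluster owns at
    least one identity coda type; re-cluster on identity-weighted similarity
    at the same cut and report the agreement (ARI) as a stability measure.
    If no cut qualifies, a single clan is returned with a note.
    """
    if len(repertoires) < 2:
        raise ValueError("need at least two repertoires")
    if similarity_mode not in ("bhattacharyya", "identity-weighted"):
        raise ValueError(f"unknown similarity mode {similarity_mode!r}")
    ids, type_ids, P = _usage_matrix(repertoires)
    _, S = similarity_matrix(repertoires, mode="bhattacharyya")
    Z = average_linkage(S, ids)
    n = len(ids)

    best_ncl, best_partition = None, None
    seen_k: set[int] = set()
    for ncl in range(n, 1, -1):
        labels = fcluster(Z, t=ncl, criterion="maxclust")
        k_eff = len(set(labels))
        if k_eff < 2 or k_eff in seen_k:
            continue
        seen_k.add(k_eff)
        if best_ncl is not None and k_eff <= best_ncl:
            break  # k_eff only shrinks as ncl decreases
        lab = np.array([str(x) for x in labels])
        idt = _detect_from_matrix(P, type_ids, lab, u_min, prevalence_min, out_max)
        owned = {r.clan_id for r in idt}
        if owned == set(lab):
            best_ncl = k_eff
            best_partition = dict(zip(ids, (int(x) for x in labels)))
            break

    if best_partition is None:
        assignment = {i: "clan_1" for i in ids}
        idt = detect_identity_types(repertoires, assignment, u_min, prevalence_min, out_max)
        return ClanAssignment(
            assignment=assignment,
            identity_types=[
                IdentityCodaResult(r.type_id, "clan_1", r.inside_usage,
                                   r.outside_usage, r.inside_prevalence)
                for r in idt
            ],
            linkage_matrix=Z,
            leaf_ids=ids,
            n_clans=1,
            stability_ari=1.0,
            note="no dendrogram cut gives every cluster an identity coda type; "
                 "single clan returned",
        )

    named = _relabel_by_size(best_partition)
    identity = detect_identity_types(repertoires, named, u_min, prevalence_min, out_max)

    # stability: re-cluster on identity-type usage only, cut at the same k
    idt_ids = sorted({r.type_id for r in identity})
    _, S2 = similarity_matrix(repertoires, "identity-weighted", idt_ids)
    Z2 = average_linkage(S2, ids)
    partition2 = cut_partition(Z2, ids, best_ncl)
    ari = float(
        adjusted_rand_score([named[i] for i in ids], [partition2[i] for i in ids])
    )
    if similarity_mode == "identity-weighted":
        named = _relabel_by_size(partition2)
        identity = detect_identity_types(
            repertoires, named, u_min, prevalence_min, out_max
        )
        Z, ids = Z2, ids
    return ClanAssignment(
        assignment=named,
        identity_types=identity,
        linkage_matrix=Z,
        leaf_ids=ids,
        n_clans=len(set(named.values())),
        stability_ari=ari,
    )


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    table: pd.DataFrame
    modal_agreement: float
    modal_partition: dict[str, str]
    ari_matrix: np.ndarray


def _canonical(partition: Mapping[str, object], ids: Sequence[str]) -> tuple:
    """Label-free canonical form: renumber clusters by first occurrence."""
    seen: dict = {}
    out = []
    for i in ids:
        c = partition[i]
        out.append(seen.setdefault(c, len(seen)))
    return tuple(out)


def sweep_parameters(
    repertoires: Sequence[UsageRepertoire],
    grid: Mapping[str, Sequence] | None = None,
) -> SweepResult:
    """Run the delineation over a threshold grid and summarize robustness.

    Reports the clan count and partition per grid point, the pairwise ARI
    matrix, and the fraction of grid points whose partition equals the modal
    (most frequent, label-free) partition.
    """
    grid = dict(SWEEP_GRID_DEFAULT, **(grid or {}))
    ids = sorted(r.repertoire_id for r in repertoires)
    rows, partitions = [], []
    for u_min, prev, out_max, mode in itertools.product(
        grid["u_min"], grid["prevalence_min"], grid["out_max"], grid["similarity_mode"]
    ):
        res = delineate_clans(
            repertoires, u_min=u_min, prevalence_min=prev,
            out_max=out_max, similarity_mode=mode,
        )
        partitions.append(res.assignment)
        rows.append(
            {
                "u_min": u_min,
                "prevalence_min": prev,
                "out_max": out_max,
                "similarity_mode": mode,
                "n_clans": res.n_clans,
                "stability_ari": res.stability_ari,
            }
        )
    canon = [_canonical(p, ids) for p in partitions]
    modal = Counter(canon).most_common(1)[0][0]
    agreement = float(np.mean([c == modal for c in canon]))
    modal_partition = partitions[canon.index(modal)]
    m = len(partitions)
    ari = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ari[i, j] = ari[j, i] = adjusted_rand_score(
                [partitions[i][x] for x in ids], [partitions[j][x] for x in ids]
            )
    table = pd.DataFrame(rows)
    table["agrees_with_modal"] = [c == modal for c in canon]
    return SweepResult(table, agreement, modal_partition, ari)


# ---------------------------------------------------------------------------
# Heat-map shading and output writers
# ---------------------------------------------------------------------------

def heatmap_bins(proportion: float) -> str:
    """Shade category for a usage proportion: white 0, light (0, 0.05],
    mid (0.05, 0.10], dark > 0.10."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if proportion == 0.0:
        return "white"
    if proportion <= 0.05:
        return "light"
    if proportion <= 0.10:
        return "mid"
    return "dark"


def heatmap_matrix(
    repertoires: Sequence[UsageRepertoire],
    identity_types: Sequence[IdentityCodaResult],
) -> pd.DataFrame:
    """Repertoire x identity-type matrix of shade categories."""
    cols = sorted({t.type_id for t in identity_types})
    reps = sorted(repertoires, key=lambda r: r.repertoire_id)
    data = {
        r.repertoire_id: [heatmap_bins(r.proportion(t)) for t in cols] for r in reps
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def write_repertoires(repertoires: Sequence[UsageRepertoire], path) -> None:
    rows = []
    for r in sorted(repertoires, key=lambda x: x.repertoire_id):
        props = r.proportions
        for t in sorted(r.counts):
            rows.append(
                {
                    "repertoire_id": r.repertoire_id,
                    "type_id": t,
                    "count": r.counts[t],
                    "proportion": f"{props[t]:.6f}",
                }
            )
    pd.DataFrame(rows, columns=["repertoire_id", "type_id", "count", "proportion"]).to_csv(
        path, index=False
    )


def write_clans(result: ClanAssignment, path) -> None:
    rows = [
        {"repertoire_id": rid, "clan_id": clan}
        for rid, clan in sorted(result.assignment.items())
    ]
    pd.DataFrame(rows, columns=["repertoire_id", "clan_id"]).to_csv(path, index=False)


def write_identity_types(types: Sequence[IdentityCodaResult], path) -> None:
    rows = [
        {
            "type_id": t.type_id,
            "clan_id": t.clan_id,
            "inside_usage": f"{t.inside_usage:.6f}",
            "outside_usage": f"{t.outside_usage:.6f}",
            "inside_prevalence": f"{t.inside_prevalence:.6f}",
        }
        for t in sorted(types, key=lambda x: (x.clan_id, x.type_id))
    ]
    pd.DataFrame(
        rows,
        columns=["type_id", "clan_id", "inside_usage", "outside_usage", "inside_prevalence"],
    ).to_csv(path, index=False)
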