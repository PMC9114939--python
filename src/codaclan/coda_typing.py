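"""Coda typing: inter-click-interval vectors, coda filters, and mixture-model
classification of codas into types.

Codas are short stereotyped click trains. Within each click-count family the
vector of absolute inter-click intervals (ICIs) is modelled as a mixture of
``k`` multivariate Gaussian components plus one broad fixed uniform
*contamination* component spanning the observed ICI bounding box; codas whose
maximum-posterior component is the contamination component are left
"unclassified". ``k`` is chosen by BIC.
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coda:
    """One click train: ordered click times in seconds."""

    coda_id: str
    source: str               # "survey" | "archive"
    date: dt.date
    group_id: str
    click_times: tuple[float, ...]

    @property
    def n_clicks(self) -> int:
        return len(self.click_times)


@dataclass(frozen=True)
class IciVector:
    coda_id: str
    n_clicks: int
    icis: tuple[float, ...]


@dataclass(frozen=True)
class CodaType:
    type_id: str
    n_clicks: int
    mean_icis: tuple[float, ...]
    label: str
    component_weight: float


@dataclass(frozen=True)
class TypeAssignment:
    coda_id: str
    type_id: str
    posterior: float


@dataclass
class TypeModel:
    """Fitted mixture for one click-count family."""

    n_clicks: int
    k: int
    types: list[CodaType]
    assignments: list[TypeAssignment]
    contamination_weight: float
    bic_by_k: dict[int, float]
    log_likelihood: float


# ---------------------------------------------------------------------------
# ICIs and filters
# ---------------------------------------------------------------------------

def compute_icis(coda: Coda) -> IciVector:
    """First differences of the click times."""
    t = np.asarray(coda.click_times, dtype=float)
    if t.size < 2:
        raise ValueError(f"coda {coda.coda_id}: needs >= 2 clicks")
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError(f"coda {coda.coda_id}: click times not strictly increasing")
    return IciVector(coda.coda_id, t.size, tuple(d))


def filter_codas(
    codas: Sequence[Coda], min_clicks: int = 3, max_clicks: int = 11
) -> tuple[list[Coda], dict[str, list[Coda]]]:
    """Keep codas with ``min_clicks <= n_clicks <= max_clicks``.

    Returns ``(kept, excluded)`` with the excluded codas keyed by reason
    ("too_short" / "too_long"), so that kept + excluded counts always
    conserve the input.
    """
    kept: list[Coda] = []
    excluded: dict[str, list[Coda]] = {"too_short": [], "too_long": []}
    for c in codas:
        if c.n_clicks < min_clicks:
            excluded["too_short"].append(c)
        elif c.n_clicks > max_clicks:
            excluded["too_long"].append(c)
        else:
            kept.append(c)
    return kept, excluded


def filter_repertoire_size(
    repertoire_counts: Mapping, min_codas: int = 25
) -> tuple[list, dict]:
    """Keep repertoires with at least ``min_codas`` codas.

    ``repertoire_counts`` maps a repertoire key to its coda count; returns
    (kept keys, dropped mapping key -> count).
    """
    for key, n in repertoire_counts.items():
        if n < 0:
            raise ValueError(f"repertoire {key}: negative count")
    kept = [k for k, n in repertoire_counts.items() if n >= min_codas]
    dropped = {k: n for k, n in repertoire_counts.items() if n < min_codas}
    return kept, dropped


# ---------------------------------------------------------------------------
# Contaminated-Gaussian mixture EM
# ---------------------------------------------------------------------------

def _component_logpdf(X, mean, var, cov=None):
    """Row-wise log density; diagonal (var) or full (cov) covariance."""
    n, d = X.shape
    if cov is None:
        return -0.5 * np.sum(
            np.log(2 * np.pi * var) + (X - mean) ** 2 / var, axis=1
        )
    sign, logdet = np.linalg.slogdet(cov)
    diff = X - mean
    sol = np.linalg.solve(cov, diff.T).T
    maha = np.einsum("ij,ij->i", diff, sol)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _em_once(X, k, seed, covariance, reg, tol, max_iter, cont_w0=0.05):
    """One EM run: k Gaussians + fixed uniform contamination component.

    Returns (loglik, weights(k), w_cont, means, vars_or_covs, resp(n,k+1)).
    """
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-2)
    # contamination: uniform over the bounding box padded by 5% per side
    log_cont = -float(np.sum(np.log(1.1 * span)))

    if k == 1:
        means = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(X)
        means = km.cluster_centers_.copy()
    global_var = X.var(axis=0) + reg
    if covariance == "diag":
        vars_ = np.tile(global_var, (k, 1))
        covs = None
    elif covariance == "full":
        covs = np.tile(np.diag(global_var), (k, 1, 1))
        vars_ = None
    else:
        raise ValueError(f"unknown covariance structure {covariance!r}")

    w = np.full(k, (1.0 - cont_w0) / k)
    w_cont = cont_w0
    prev_ll = -np.inf
    log_r = np.empty((n, k + 1))
    for _ in range(max_iter):
        for j in range(k):
            log_r[:, j] = np.log(w[j]) + _component_logpdf(
                X, means[j], vars_[j] if covs is None else None,
                None if covs is None else covs[j],
            )
        log_r[:, k] = np.log(max(w_cont, 1e-300)) + log_cont
        norm = logsumexp(log_r, axis=1)
        ll = float(norm.sum())
        resp = np.exp(log_r - norm[:, None])
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        nk = resp[:, :k].sum(axis=0)
        w = nk / n
        w_cont = float(resp[:, k].sum() / n)
        for j in range(k):
            if nk[j] < 1e-10:
                continue  # dying component: keep previous parameters
            means[j] = resp[:, j] @ X / nk[j]
            diff = X - means[j]
            if covs is None:
                vars_[j] = resp[:, j] @ diff**2 / nk[j] + reg
            else:
                covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
                covs[j][np.diag_indices(d)] += reg
    return prev_ll, w, w_cont, means, (vars_ if covs is None else covs), resp


def _n_params(k: int, d: int, covariance: str) -> int:
    cov_p = k * d if covariance == "diag" else k * d * (d + 1) // 2
    return k * d + cov_p + k  # means + covariances + free mixing weights


def fit_type_model(
    icivectors: Sequence[IciVector],
    k_max: int = 15,
    seed: int = 0,
    covariance: str = "diag",
    reg: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> TypeModel:
    """Fit the contaminated mixture for one click-count family and classify.

    Model order ``k`` is selected by BIC over ``k = 1..k_max`` (the search
    stops early after three consecutive BIC increases past the best model).
    Components are re-ordered lexicographically by mean ICI vector so that
    type identifiers "<n_clicks>-<index>" are deterministic.
    """
    if not icivectors:
        raise ValueError("empty input")
    d = len(icivectors[0].icis)
    if any(len(v.icis) != d for v in icivectors):
        raise ValueError("mixed ICI dimensions in one family")
    n_clicks = d + 1
    X = np.array([v.icis for v in icivectors], dtype=float)
    n = X.shape[0]
    if n < 2 * d:
        raise ValueError(
            f"family of {n_clicks}-click codas: {n} vectors < {2 * d} required"
        )

    bic_by_k: dict[int, float] = {}
    best = None
    rises = 0
    for k in range(1, k_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _em_once(X, k, seed + k, covariance, reg, tol, max_iter)
        ll = fit[0]
        bic = -2.0 * ll + _n_params(k, d, covariance) * np.log(n)
        bic_by_k[k] = bic
        if best is None or bic < bic_by_k[best[0]]:
            best = (k, fit)
            rises = 0
        else:
            rises += 1
            if rises >= 3:
                break

    k, (ll, w, w_cont, means, _cov, resp) = best
    order = np.lexsort(means.T[::-1])  # lexicographic by mean vector
    types = []
    for rank, j in enumerate(order, start=1):
        types.append(
            CodaType(
                type_id=f"{n_clicks}-{rank}",
                n_clicks=n_clicks,
                mean_icis=tuple(float(x) for x in means[j]),
                label=label_type(means[j]),
                component_weight=float(w[j]),
            )
        )
    col_of = {j: rank for rank, j in enumerate(order)}

    assignments = []
    for i, v in enumerate(icivectors):
        j = int(np.argmax(resp[i]))
        if j == k:
            assignments.append(TypeAssignment(v.coda_id, UNCLASSIFIED, float(resp[i, k])))
        else:
            assignments.append(
                TypeAssignment(v.coda_id, types[col_of[j]].type_id, float(resp[i, j]))
            )
    return TypeModel(
        n_clicks=n_clicks,
        k=k,
        types=types,
        assignments=assignments,
        contamination_weight=float(w_cont),
        bic_by_k=bic_by_k,
        log_likelihood=float(ll),
    )


@dataclass
class CodaTypingResult:
    models: dict[int, TypeModel]            # keyed by click count
    types: list[CodaType]
    assignment: dict[str, TypeAssignment]   # keyed by coda_id
    n_unfit: int                            # codas in families too small to fit

    @property
    def label_of(self) -> dict[str, str]:
        return {t.type_id: t.label for t in self.types}


def classify_codas(
    codas: Sequence[Coda], k_max: int = 15, seed: int = 42, **fit_kwargs
) -> CodaTypingResult:
    """Pool all codas, split by click count, fit each family, classify.

    Families with fewer than ``2 * (n_clicks - 1)`` codas cannot support a
    fit; their codas are assigned "unclassified".
    """
    families: dict[int, list[IciVector]] = defaultdict(list)
    for c in codas:
        v = compute_icis(c)
        families[v.n_clicks].append(v)

    models: dict[int, TypeModel] = {}
    types: list[CodaType] = []
    assignment: dict[str, TypeAssignment] = {}
    n_unfit = 0
    for n_clicks in sorted(families):
        vecs = families[n_clicks]
        try:
            model = fit_type_model(vecs, k_max=k_max, seed=seed + n_clicks, **fit_kwargs)
        except ValueError:
            n_unfit += len(vecs)
            for v in vecs:
                assignment[v.coda_id] = TypeAssignment(v.coda_id, UNCLASSIFIED, 1.0)
            continue
        models[n_clicks] = model
        types.extend(model.types)
        for a in model.assignments:
            assignment[a.coda_id] = a
    return CodaTypingResult(models, types, assignment, n_unfit)


# ---------------------------------------------------------------------------
# Human-readable type labels
# ---------------------------------------------------------------------------

def label_type(
    mean_icis: Sequence[float], regular_tol: float = 0.15, gap_ratio: float = 1.8
) -> str:
    """Field-style rhythm label for a coda type.

    Regular types ("5R") have all mean ICIs within ``regular_tol`` of each
    other; otherwise the click train is split wherever an ICI exceeds
    ``gap_ratio`` times the minimum ICI and labelled by the "+"-joined
    sub-group sizes (e.g. "1+1+3").
    """
    icis = np.asarray(mean_icis, dtype=float)
    if icis.size == 0:
        raise ValueError("empty mean ICI vector")
    n_clicks = icis.size + 1
    if icis.max() / icis.min() <= 1.0 + regular_tol:
        return f"{n_clicks}R"
    threshold = gap_ratio * icis.min()
    sizes = []
    current = 1
    for ici in icis:
        if ici > threshold:
            sizes.append(current)
            current = 1
        else:
            current += 1
    sizes.append(current)
    return "+".join(str(s) for s in sizes)


# ---------------------------------------------------------------------------
# CSV I/O (codas.csv = coda_id,source,date,group_id,click_times with
# semicolon-separated seconds)
# ---------------------------------------------------------------------------

def write_codas(codas: Sequence[Coda], path) -> None:
    rows = [
        {
            "coda_id": c.coda_id,
            "source": c.source,
            "date": c.date.isoformat(),
            "group_id": c.group_id,
            "click_times": ";".join(f"{t:.6f}" for t in c.click_times),
        }
        for c in codas
    ]
    pd.DataFrame(
        rows, columns=["coda_id", "source", "date", "group_id", "click_times"]
    ).to_csv(path, index=False)


def read_codas(path) -> list[Coda]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for i, row in df.iterrows():
        try:
            clicks = tuple(float(x) for x in str(row["click_times"]).split(";"))
            out.append(
                Coda(
                    coda_id=str(row["coda_id"]),
                    source=str(row["source"]),
                    date=dt.date.fromisoformat(str(row["date"])),
                    group_id=str(row["group_id"]),
                    click_times=clicks,
                )
            )
        except ValueError as exc:
            raise ValueError(f"codas row {i}: {exc}") from exc
    return out


def write_types(types: Sequence[CodaType], path) -> None:
    rows = [
        {
            "type_id": t.type_id,
            "n_clicks": t.n_clicks,
            "label": t.label,
            "component_weight": f"{t.component_weight:.6f}",
            "mean_icis": ";".join(f"{x:.6f}" for x in t.mean_icis),
        }
        for t in types
    ]
    pd.DataFrame(
        rows, columns=["type_id", "n_clicks", "label", "component_weight", "mean_icis"]
    ).to_csv(path, index=False)


def write_assignments(assignments: Mapping[str, TypeAssignment], path) -> None:
    rows = [
        {
            "coda_id": a.coda_id,
            "type_id": a.type_id,
            "posterior": f"{a.posterior:.6f}",
        }
        for a in (assignments[k] for k in sorted(assignments))
    ]
    pd.DataFrame(rows, columns=["coda_id", "type_id", "posterior"]).to_csv(
        path, index=False
    )
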