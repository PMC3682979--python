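"""Soft temporal clustering of TF expression profiles.

The pipeline filters out never-expressed and near-constant TFs, Z-normalizes
each remaining profile to mean 0 / sd 1, and runs fuzzy c-means with c=7
clusters and fuzzifier m=1.25. Genes whose maximal membership exceeds 0.8
are hard-assigned to that cluster; family composition per cluster is then
tested with two one-sided hypergeometric tests at alpha=0.0025.

The fuzzy c-means estimator follows the classic Bezdek alternating scheme:

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))
    v_i  = sum_k u_ik^m x_k / sum_k u_ik^m

with Euclidean d, stopping when the largest membership change falls below
``tol``. A point coinciding with a center receives membership 1 there. With
m close to 1 the memberships harden and the method approaches k-means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse, PresenceTable, TFCatalog
from .utilization import hypergeometric_overlap

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_for_clustering(
    x: ExpressionTimeCourse,
    p: PresenceTable | None = None,
    min_range: float = 1.0,
) -> ExpressionTimeCourse:
    """Drop never-expressed and near-constant genes before clustering.

    A gene is dropped if (a) it is absent at every time point of the
    presence table, or (b) its max expression is less than ``min_range``
    above its min on the log2 scale (i.e. less than two-fold dynamic range).
    A range of exactly ``min_range`` is retained (the rule is strict
    "less than").
    """
    keep = pd.Series(True, index=x.values.index)
    n_never = 0
    if p is not None:
        ever = p.ever_present()
        common = x.values.index.intersection(ever.index)
        never = common[~ever.loc[common].to_numpy()]
        keep.loc[never] = False
        n_never = len(never)
    rng = x.values.max(axis=1) - x.values.min(axis=1)
    constant = keep & (rng < min_range)
    n_constant = int(constant.sum())
    keep &= ~constant
    if not keep.any():
        raise ValueError("all genes filtered out before clustering")
    out = ExpressionTimeCourse(x.species, x.values.loc[keep], dict(x.meta))
    out.meta["n_dropped_never_expressed"] = n_never
    out.meta["n_dropped_constant"] = n_constant
    log.info(
        "filter_for_clustering: dropped %d never-expressed, %d constant; %d kept",
        n_never, n_constant, int(keep.sum()),
    )
    return out


def z_normalize(x: ExpressionTimeCourse) -> ExpressionTimeCourse:
    """Row-wise standardization to mean 0, sd 1 (population sd, denominator T)."""
    vals = x.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # ddof=0
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValueError(f"zero-variance profile for gene {x.genes[zero[0]]!r}")
    out = ExpressionTimeCourse(
        x.species,
        pd.DataFrame((vals - mean) / sd, index=x.values.index, columns=x.values.columns),
        dict(x.meta),
    )
    out.meta["normalization"] = "z-score (population sd)"
    return out


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    """Fitted fuzzy c-means result.

    ``centers`` is c x T in Z-space; ``membership`` is n x c with rows
    summing to 1; ``objective_trace`` records J = sum u^m d^2 per iteration
    of the winning restart.
    """

    centers: np.ndarray
    membership: pd.DataFrame
    m: float
    objective_trace: list[float]
    seed: int
    n_iter: int
    converged: bool
    meta: dict = field(default_factory=dict)

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def summary(self) -> str:
        a = assign_members(self)
        sizes = pd.Series(a.labels).value_counts().sort_index()
        lines = [
            f"Fuzzy c-means: c={self.c}, m={self.m}, n={self.membership.shape[0]}",
            f"objective={self.objective:.4f}  iterations={self.n_iter}  "
            f"converged={self.converged}  seed={self.seed}",
            "cluster sizes at membership > %.2f:" % a.threshold,
        ]
        for cid, sz in sizes.items():
            lines.append(f"  cluster {cid}: {sz}")
        lines.append(f"  unassigned: {len(a.unassigned)}")
        return "\n".join(lines)


_ZERO_DIST = 1e-12


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (n x c)."""
    exponent = 1.0 / (m - 1.0)
    u = np.zeros_like(d2)
    zero_rows = d2.min(axis=1) < _ZERO_DIST
    if zero_rows.any():
        # a point on a center belongs there entirely (ties split equally)
        hits = d2[zero_rows] < _ZERO_DIST
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if ok.any():
        inv = d2[ok] ** (-exponent)
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _objective(x: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def _kmeanspp_centers(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers over the data."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _fcm_single(
    x: np.ndarray,
    c: int,
    m: float,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    init: str = "kmeans++",
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    n = x.shape[0]
    if init == "kmeans++":
        centers0 = _kmeanspp_centers(x, c, rng)
        d2 = ((x[:, None, :] - centers0[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
    elif init == "random":
        u = rng.random((n, c))
        u /= u.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown init {init!r}")
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u_new = _memberships(d2, m)
        trace.append(float(((u_new ** m) * d2).sum()))
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            converged = True
            break
    um = u ** m
    centers = (um.T @ x) / um.sum(axis=0)[:, None]
    return centers, u, trace, it, converged


def fuzzy_cmeans(
    x: ExpressionTimeCourse | pd.DataFrame | np.ndarray,
    c: int = 7,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 10,
    init: str = "kmeans++",
) -> FuzzyClustering:
    """Fuzzy c-means clustering of Z-normalized temporal profiles.

    Initialization is k-means++ center seeding by default (memberships then
    derived from the seeded centers), which avoids the local optima that
    plague uniform random memberships at small fuzzifiers; ``init="random"``
    gives the classic row-normalized uniform memberships. The best of
    ``n_restarts`` runs by final objective is returned, so the result is
    deterministic given the seed.
    """
    if isinstance(x, ExpressionTimeCourse):
        df = x.values
    elif isinstance(x, pd.DataFrame):
        df = x
    else:
        arr = np.asarray(x, dtype=float)
        df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])])
    data = df.to_numpy(dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in clustering input")
    n = data.shape[0]
    if n <= c:
        raise ValueError(f"need more points ({n}) than clusters ({c})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    best = None
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in children:
        rng = np.random.default_rng(ss)
        result = _fcm_single(data, c, m, tol, max_iter, rng, init=init)
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    centers, u, trace, it, converged = best
    if not converged:
        log.warning("fuzzy_cmeans: best restart did not converge in %d iterations", it)
    membership = pd.DataFrame(u, index=df.index, columns=list(range(c)))
    return FuzzyClustering(
        centers=centers,
        membership=membership,
        m=m,
        objective_trace=trace,
        seed=seed,
        n_iter=it,
        converged=converged,
        meta={"c": c, "tol": tol, "n_restarts": n_restarts, "init": init},
    )


# ---------------------------------------------------------------------------
# hard assignment and family enrichment
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Hard cluster membership at a membership threshold (strict >)."""

    labels: dict[str, int]
    unassigned: list[str]
    threshold: float

    @property
    def genes(self) -> list[str]:
        return list(self.labels)

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def members_of(self, cluster: int) -> list[str]:
        return [g for g, cid in self.labels.items() if cid == cluster]

    def __len__(self) -> int:
        return len(self.labels)


def assign_members(f: FuzzyClustering, threshold: float = 0.8) -> ClusterAssignment:
    """Assign genes whose maximal membership strictly exceeds the threshold."""
    if not (1.0 / f.c < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (1/c, 1], got {threshold}")
    u = f.membership.to_numpy()
    argmax = u.argmax(axis=1)
    maxval = u.max(axis=1)
    labels = {}
    unassigned = []
    for gene, cid, v in zip(f.membership.index, argmax, maxval):
        if v > threshold:
            labels[gene] = int(cid)
        else:
            unassigned.append(gene)
    return ClusterAssignment(labels, unassigned, threshold)


def cluster_family_enrichment(
    a: ClusterAssignment,
    cat: TFCatalog,
    alpha: float = 0.0025,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric family representation test per (cluster, family).

    The background universe is the set of assigned genes (the clustered
    TFs), mirroring representation within clusters. For each cluster and
    family, k = family members in the cluster, n = cluster size, K = family
    members among assigned genes, N = assigned genes; both one-sided tails
    are reported and flagged at ``alpha``.
    """
    if not a.labels:
        raise ValueError("no assigned genes")
    assigned = set(a.labels)
    N = len(assigned)
    if families is None:
        families = cat.families
    rows = []
    for fam in families:
        members = set(cat.members_of(fam)) & assigned
        K = len(members)
        if K == 0:
            continue
        for cid in a.clusters:
            in_cluster = set(a.members_of(cid))
            n = len(in_cluster)
            k = len(members & in_cluster)
            p_over, p_under = hypergeometric_overlap(k, n, K, N)
            rows.append(
                {
                    "cluster": cid, "family": fam,
                    "k": k, "n": n, "K": K, "N": N,
                    "p_over": p_over, "p_under": p_under,
                    "over": p_over < alpha, "under": p_under < alpha,
                }
            )
    return pd.DataFrame(rows)
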