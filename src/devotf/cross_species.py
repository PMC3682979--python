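"""Cross-species comparison of expression clusters.

Two species' time courses are restricted to manually aligned time points,
Euclidean distances between cluster centers are computed on the common
grid, and clusters are paired when a cross-species pair of centers is
mutually closer to each other than either is to any other cluster of either
species (the strict combined-set reading). A dendrogram over the combined
2c centers (average linkage) accompanies the pairing, and family
composition across the paired clusters is compared with an exact
(enumerated) or Monte-Carlo Fisher test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .containers import ExpressionTimeCourse, TFCatalog, TimeAlignment
from .clustering import ClusterAssignment
from .utilization import hypergeometric_overlap

log = logging.getLogger(__name__)


def restrict_to_alignment(
    xa: ExpressionTimeCourse | np.ndarray,
    xb: ExpressionTimeCourse | np.ndarray,
    al: TimeAlignment,
) -> tuple[np.ndarray, np.ndarray]:
    """Select the aligned columns of both matrices, in alignment order."""
    if isinstance(xa, ExpressionTimeCourse):
        idx = al.indices(xa.time_points, xb.time_points)
        ma, mb = xa.values.to_numpy(), xb.values.to_numpy()
    else:
        ma, mb = np.asarray(xa), np.asarray(xb)
        idx = al.indices(
            [str(i) for i in range(ma.shape[1])], [str(i) for i in range(mb.shape[1])]
        )
    ia = [i for i, _ in idx]
    ib = [j for _, j in idx]
    if max(ia) >= ma.shape[1] or max(ib) >= mb.shape[1]:
        raise ValueError("alignment index out of range")
    return ma[:, ia], mb[:, ib]


def cluster_center_distances(centers_a: np.ndarray, centers_b: np.ndarray) -> np.ndarray:
    """Euclidean distances between every A-center and every B-center."""
    a = np.asarray(centers_a, dtype=float)
    b = np.asarray(centers_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"center dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return cdist(a, b)


@dataclass
class ClusterPairing:
    """1-to-1 cross-species cluster pairs plus the display dendrogram."""

    pairs: list[tuple[int, int, float]]
    unpaired_a: list[int]
    unpaired_b: list[int]
    linkage: np.ndarray | None = None
    leaf_labels: list[str] = field(default_factory=list)
    ties: list[tuple[int, int]] = field(default_factory=list)
    mode: str = "combined"

    @property
    def mapping(self) -> dict[int, int]:
        return {i: j for i, j, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def to_newick(self) -> str:
        """Newick rendering of the average-linkage tree over the 2c centers."""
        if self.linkage is None:
            raise ValueError("no linkage tree computed")
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_dist: float) -> str:
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{parent_dist:.6g}"
            inner = ",".join(
                render(ch, node.dist) for ch in (node.get_left(), node.get_right())
            )
            return f"({inner}):{parent_dist - node.dist:.6g}"

        inner = ",".join(
            render(ch, tree.dist) for ch in (tree.get_left(), tree.get_right())
        )
        return f"({inner});"


def pair_clusters(
    centers_a: np.ndarray,
    centers_b: np.ndarray,
    mode: str = "combined",
    labels_a: str = "A",
    labels_b: str = "B",
) -> ClusterPairing:
    """Pair clusters across species by mutual nearest centers.

    ``mode="combined"`` (default, strictest reading): (i, j) pair iff their
    distance is strictly smaller than the distance from i or from j to ANY
    other cluster of either species. ``mode="within-rows"`` relaxes the
    predicate to mutual row/column minima of the cross matrix. Exact
    distance ties among the candidates reject the pairing (logged).
    """
    a = np.asarray(centers_a, dtype=float)
    b = np.asarray(centers_b, dtype=float)
    D = cluster_center_distances(a, b)
    Daa = cdist(a, a)
    Dbb = cdist(b, b)
    ca, cb = D.shape
    pairs: list[tuple[int, int, float]] = []
    ties: list[tuple[int, int]] = []
    for i in range(ca):
        j = int(np.argmin(D[i]))
        d = D[i, j]
        competitors = np.concatenate(
            [
                np.delete(D[i], j),          # i to other B clusters
                np.delete(D[:, j], i),       # j to other A clusters
            ]
        )
        if mode == "combined":
            competitors = np.concatenate(
                [competitors, np.delete(Daa[i], i), np.delete(Dbb[j], j)]
            )
        elif mode != "within-rows":
            raise ValueError(f"unknown pairing mode {mode!r}")
        if competitors.size and (competitors == d).any():
            ties.append((i, j))
            log.warning("pair_clusters: exact tie at (%d, %d); no pair formed", i, j)
            continue
        if competitors.size == 0 or d < competitors.min():
            pairs.append((i, j, float(d)))
    paired_a = {i for i, _, _ in pairs}
    paired_b = {j for _, j, _ in pairs}
    unpaired_a = [i for i in range(ca) if i not in paired_a]
    unpaired_b = [j for j in range(cb) if j not in paired_b]

    combined = np.vstack([a, b])
    linkage = hierarchy.linkage(combined, method="average") if len(combined) > 1 else None
    leaf_labels = [f"{labels_a}{i}" for i in range(ca)] + [f"{labels_b}{j}" for j in range(cb)]
    return ClusterPairing(pairs, unpaired_a, unpaired_b, linkage, leaf_labels, ties, mode)


# ---------------------------------------------------------------------------
# family composition across species
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray) -> float:
    """Log probability of a 2 x k table under fixed margins (multivariate
    hypergeometric)."""
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    N = int(table.sum())
    lp = -math.lgamma(N + 1) + math.lgamma(n1 + 1) + math.lgamma(N - n1 + 1)
    for j in range(table.shape[1]):
        c = int(col[j])
        a = int(table[0, j])
        lp += (
            math.lgamma(c + 1)
            - math.lgamma(a + 1)
            - math.lgamma(c - a + 1)
        )
    return lp


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact two-sided Fisher test for a 2 x k table by full enumeration.

    Sums the probability of every table with the observed margins whose
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=int)
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    lp_obs = _table_log_prob(table)
    total = 0.0
    k = table.shape[1]

    ranges = [range(int(c) + 1) for c in col[:-1]]
    for combo in itertools.product(*ranges):
        rest = n1 - sum(combo)
        if rest < 0 or rest > col[-1]:
            continue
        cand = np.vstack([list(combo) + [rest], col - np.array(list(combo) + [rest])])
        lp = _table_log_prob(cand)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def fisher_montecarlo_2xk(
    table: np.ndarray, n_mc: int = 10000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher p for a 2 x k table under fixed margins.

    Draws ``n_mc`` tables by randomly splitting each column's total between
    the rows via a hypergeometric chain, and reports the add-one fraction of
    tables at most as probable as the observed one.
    """
    table = np.asarray(table, dtype=int)
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    N = int(table.sum())
    lp_obs = _table_log_prob(table)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        remaining_n1 = n1
        remaining_N = N
        row1 = np.zeros_like(col)
        for j, c in enumerate(col[:-1]):
            draw = rng.hypergeometric(remaining_n1, remaining_N - remaining_n1, c)
            row1[j] = draw
            remaining_n1 -= draw
            remaining_N -= c
        row1[-1] = remaining_n1
        cand = np.vstack([row1, col - row1])
        if _table_log_prob(cand) <= lp_obs + 1e-9:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def family_distribution_test(
    a_assign: ClusterAssignment,
    b_assign: ClusterAssignment,
    pairing: ClusterPairing,
    cat_a: TFCatalog,
    cat_b: TFCatalog,
    families: list[str] | None = None,
    exact_limit: int = 200,
    n_mc: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-family Fisher test of cluster-pair composition across species.

    For each family, builds a 2 x (paired clusters) table of that family's
    assigned members per cluster pair in each species, and tests whether the
    distribution differs between species (exact enumeration when the table
    total is at most ``exact_limit``, Monte Carlo otherwise).
    """
    if len(pairing) < 2:
        raise ValueError("need at least 2 paired clusters")
    if families is None:
        families = sorted(set(cat_a.families) & set(cat_b.families))
    rows = []
    for fam in families:
        fam_a = set(cat_a.members_of(fam))
        fam_b = set(cat_b.members_of(fam))
        counts_a, counts_b = [], []
        for i, j, _ in pairing.pairs:
            counts_a.append(len(fam_a & set(a_assign.members_of(i))))
            counts_b.append(len(fam_b & set(b_assign.members_of(j))))
        table = np.array([counts_a, counts_b], dtype=int)
        if table.sum() == 0:
            log.info("family %s has no assigned members in either species; skipped", fam)
            continue
        nonzero = table.sum(axis=0) > 0
        table = table[:, nonzero]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            p, method = 1.0, "degenerate"
        elif table.sum() <= exact_limit:
            p, method = fisher_exact_2xk(table), "exact"
        else:
            p, method = fisher_montecarlo_2xk(table, n_mc=n_mc, seed=seed), "montecarlo"
        rows.append({"family": fam, "p": p, "method": method, "total": int(table.sum())})
    return pd.DataFrame(rows)


def pair_family_enrichment(
    pairing: ClusterPairing,
    a_assign: ClusterAssignment,
    b_assign: ClusterAssignment,
    cat_a: TFCatalog,
    cat_b: TFCatalog,
    alpha: float = 0.0025,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Family representation per cluster pair, pooling both species.

    The members of each cluster pair from both species are tested against
    the pooled assigned background with two one-sided hypergeometric tails
    at ``alpha``, as for the single-species cluster test.
    """
    if not pairing.pairs:
        raise ValueError("empty pairing")
    if families is None:
        families = sorted(set(cat_a.families) | set(cat_b.families))
    # pooled universes; gene ids get a species prefix to avoid collisions
    assigned = [("a", g) for g in a_assign.labels] + [("b", g) for g in b_assign.labels]
    N = len(assigned)
    fam_members = {
        fam: {("a", g) for g in cat_a.members_of(fam)}
        | {("b", g) for g in cat_b.members_of(fam)}
        for fam in families
    }
    rows = []
    for fam in families:
        members = fam_members[fam] & set(assigned)
        K = len(members)
        if K == 0:
            continue
        for idx, (i, j, dist) in enumerate(pairing.pairs):
            pool = {("a", g) for g in a_assign.members_of(i)} | {
                ("b", g) for g in b_assign.members_of(j)
            }
            n = len(pool)
            k = len(members & pool)
            p_over, p_under = hypergeometric_overlap(k, n, K, N)
            rows.append(
                {
                    "pair": idx, "cluster_a": i, "cluster_b": j, "family": fam,
                    "k": k, "n": n, "K": K, "N": N,
                    "p_over": p_over, "p_under": p_under,
                    "over": p_over < alpha, "under": p_under < alpha,
                }
            )
    return pd.DataFrame(rows)
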