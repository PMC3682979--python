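"""Ortholog-level expression conservation statistics.

Two observed statistics are compared against permutation nulls built from
1,000 sets of random cross-species gene pairs:

* cluster concordance — the number of ortholog pairs whose two genes fall
  into clusters that are paired across the species;
* correlation count — the number of ortholog pairs whose expression over the
  common (aligned) time points is significantly correlated.

Each null set redraws the same number of pairs uniformly (with replacement)
from the eligible gene universes; the report carries
Z = (observed - mean(null)) / sd(null) and the add-one empirical p-value
(1 + #{null >= observed}) / (n_sets + 1), so p is never smaller than
1/(n_sets + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OrthologMap
from .clustering import ClusterAssignment
from .cross_species import ClusterPairing


@dataclass
class PermutationNullResult:
    """Observed statistic against a random-pair null distribution."""

    observed: float
    null_values: np.ndarray
    n_sets: int
    seed: int
    statistic: str = ""

    @property
    def z_score(self) -> float:
        sd = float(np.std(self.null_values, ddof=1))
        if sd == 0:
            return float("nan")
        return (self.observed - float(np.mean(self.null_values))) / sd

    @property
    def empirical_p(self) -> float:
        b = int(np.sum(np.asarray(self.null_values) >= self.observed))
        return (1 + b) / (self.n_sets + 1)

    def summary(self) -> dict:
        z = self.z_score
        return {
            "statistic": self.statistic,
            "observed": float(self.observed),
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)),
            "z": None if np.isnan(z) else float(z),
            "empirical_p": float(self.empirical_p),
            "n_sets": self.n_sets,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# cluster concordance
# ---------------------------------------------------------------------------

def ortholog_cluster_concordance(
    om: OrthologMap,
    a_assign: ClusterAssignment,
    b_assign: ClusterAssignment,
    pairing: ClusterPairing,
) -> tuple[int, int]:
    """Count ortholog pairs falling into analogous (paired) clusters.

    Eligible pairs have both genes hard-assigned to some cluster; a pair is
    concordant when its two clusters form a cross-species pair.
    Returns ``(n_concordant, n_eligible)``.
    """
    mapping = pairing.mapping
    n_eligible = 0
    n_concordant = 0
    for ga, gb in om.pairs:
        ca = a_assign.labels.get(ga)
        cb = b_assign.labels.get(gb)
        if ca is None or cb is None:
            continue
        n_eligible += 1
        if mapping.get(ca) == cb:
            n_concordant += 1
    return n_concordant, n_eligible


def concordance_null(
    om: OrthologMap,
    a_assign: ClusterAssignment,
    b_assign: ClusterAssignment,
    pairing: ClusterPairing,
    n_sets: int = 1000,
    seed: int = 0,
) -> PermutationNullResult:
    """Random-pair null for the concordance count.

    Each null set draws ``n_eligible`` pairs by sampling an assigned gene
    from each species uniformly and independently (with replacement), and
    counts how many land in paired clusters.
    """
    observed, n_eligible = ortholog_cluster_concordance(om, a_assign, b_assign, pairing)
    if n_eligible < 1:
        raise ValueError("no eligible ortholog pairs")
    rng = np.random.default_rng(seed)
    labels_a = np.array([a_assign.labels[g] for g in a_assign.labels])
    labels_b = np.array([b_assign.labels[g] for g in b_assign.labels])
    # map each A cluster to its paired B cluster (or -1)
    max_cluster = int(labels_a.max()) if labels_a.size else 0
    partner = np.full(max_cluster + 1, -1)
    for i, j in pairing.mapping.items():
        if i <= max_cluster:
            partner[i] = j
    ia = rng.integers(0, len(labels_a), size=(n_sets, n_eligible))
    ib = rng.integers(0, len(labels_b), size=(n_sets, n_eligible))
    null = (partner[labels_a[ia]] == labels_b[ib]).sum(axis=1)
    return PermutationNullResult(
        observed=float(observed),
        null_values=null.astype(float),
        n_sets=n_sets,
        seed=seed,
        statistic="n_concordant",
    )


# ---------------------------------------------------------------------------
# expression correlation
# ---------------------------------------------------------------------------

def _unit_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (unit rows, ok mask)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def ortholog_correlations(
    om: OrthologMap,
    za: pd.DataFrame,
    zb: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
) -> tuple[int, int, pd.DataFrame]:
    """Per-pair expression correlation over the common time points.

    ``za`` and ``zb`` are gene x aligned-time-point matrices with equal
    column counts. Pairs with a constant profile in the common window are
    skipped (correlation undefined). Returns
    ``(n_significant, n_tested, per-pair table)``.
    """
    if za.shape[1] != zb.shape[1]:
        raise ValueError("aligned matrices must share their column count")
    T = za.shape[1]
    if T < 3:
        raise ValueError("need at least 3 common time points")
    rows = []
    for ga, gb in om.pairs:
        if ga not in za.index or gb not in zb.index:
            continue
        xa = za.loc[ga].to_numpy(dtype=float)
        xb = zb.loc[gb].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append({"gene_a": ga, "gene_b": gb, "r": np.nan, "p": np.nan,
                         "note": "constant profile"})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(xa, xb)
        elif method == "spearman":
            r, p = stats.spearmanr(xa, xb)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append({"gene_a": ga, "gene_b": gb, "r": float(r), "p": float(p), "note": ""})
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "note"])
    tested = table[table["note"] == ""]
    n_tested = len(tested)
    n_significant = int((tested["p"] < alpha).sum())
    return n_significant, n_tested, table


def correlation_null(
    om: OrthologMap,
    za: pd.DataFrame,
    zb: pd.DataFrame,
    alpha: float = 0.05,
    n_sets: int = 1000,
    seed: int = 0,
) -> PermutationNullResult:
    """Random-pair null for the count of significantly correlated pairs.

    Null pairs are drawn from the genes of the two aligned matrices (the
    same universe as the observed statistic) on the same common grid.
    """
    n_sig, n_tested, _ = ortholog_correlations(om, za, zb, alpha=alpha)
    if n_tested < 1:
        raise ValueError("no testable ortholog pairs")
    T = za.shape[1]
    ua, ok_a = _unit_rows(za.to_numpy(dtype=float))
    ub, ok_b = _unit_rows(zb.to_numpy(dtype=float))
    ua, ub = ua[ok_a], ub[ok_b]
    # |r| threshold equivalent to the two-sided t test at alpha
    df = T - 2
    t_crit = stats.t.isf(alpha / 2, df)
    r_crit = t_crit / np.sqrt(df + t_crit ** 2)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, ua.shape[0], size=(n_sets, n_tested))
    ib = rng.integers(0, ub.shape[0], size=(n_sets, n_tested))
    r = np.einsum("stk,stk->st", ua[ia], ub[ib])
    null = (np.abs(r) > r_crit).sum(axis=1)
    return PermutationNullResult(
        observed=float(n_sig),
        null_values=null.astype(float),
        n_sets=n_sets,
        seed=seed,
        statistic="n_correlated",
    )
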