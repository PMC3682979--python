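"""TF utilization across developmental stages.

Computes the fraction of catalog TFs called present at each time point, the
same fraction per structural family, and each family's representation
relative to all TFs — the machinery behind "percent of TFs expressed"
trajectories. Over/under-representation at this level is descriptive; formal
hypergeometric testing happens in cluster space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PresenceTable, TFCatalog

log = logging.getLogger(__name__)


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """One-sided hypergeometric tail probabilities for an overlap of size k.

    Drawing ``n`` items from a universe of ``N`` containing ``K`` marked
    items, returns ``(P(X >= k), P(X <= k))`` for X hypergeometric. The two
    tails share the point mass at ``k``, so they sum to at least 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible counts: k={k} n={n} K={K} N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} infeasible for n={n} K={K} N={N}")
    dist = stats.hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))
    p_under = float(dist.cdf(k))
    return min(p_over, 1.0), min(p_under, 1.0)


def percent_expressed(p: PresenceTable, genes) -> pd.Series:
    """Fraction of the given genes called present at each time point.

    Genes missing from the presence table are logged and dropped; the
    denominator is the number of genes with data.
    """
    genes = list(dict.fromkeys(genes))
    have = [g for g in genes if g in p.values.index]
    n_missing = len(genes) - len(have)
    if n_missing:
        log.info("percent_expressed: %d genes without presence data dropped", n_missing)
    if not have:
        raise ValueError("no overlap between gene set and presence table")
    sub = p.values.loc[have]
    return sub.sum(axis=0) / len(have)


@dataclass
class UtilizationProfile:
    """Per-stage TF utilization summary for one species."""

    species: str
    time_points: list[str]
    overall_fraction: pd.Series
    per_family_fraction: pd.DataFrame      # family x time
    relative_representation: pd.DataFrame  # family x time
    family_sizes: dict[str, int] = field(default_factory=dict)
    gastrulation_index: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready layout: one row per time point."""
        out = pd.DataFrame({"time": self.time_points, "overall": self.overall_fraction.values})
        for fam in self.per_family_fraction.index:
            out[f"{fam}_fraction"] = self.per_family_fraction.loc[fam].values
            out[f"{fam}_relative"] = self.relative_representation.loc[fam].values
        return out


def family_representation(
    p: PresenceTable,
    cat: TFCatalog,
    min_family_size: int = 5,
    gastrulation_index: int | None = None,
) -> UtilizationProfile:
    """Per-family expressed fractions and representation relative to all TFs.

    Relative representation of family F at time t is
    ``(fraction_F(t) - fraction_all(t)) / fraction_all(t)``; genes belonging
    to several families count once per family. Families with fewer than
    ``min_family_size`` members with data are skipped.
    """
    catalog_genes = [g for g in cat.genes if g in p.values.index]
    if not catalog_genes:
        raise ValueError("no catalog genes with presence data")
    overall = percent_expressed(p, catalog_genes)

    fractions = {}
    sizes = {}
    for fam in cat.families:
        members = [g for g in cat.members_of(fam) if g in p.values.index]
        if len(members) < min_family_size:
            log.info("family %s skipped (%d members with data)", fam, len(members))
            continue
        fractions[fam] = percent_expressed(p, members)
        sizes[fam] = len(members)
    per_family = pd.DataFrame(fractions).T
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (per_family - overall) / overall
    return UtilizationProfile(
        species=p.species,
        time_points=p.time_points,
        overall_fraction=overall,
        per_family_fraction=per_family,
        relative_representation=rel,
        family_sizes=sizes,
        gastrulation_index=gastrulation_index,
    )
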