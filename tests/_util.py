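"""Shared helpers for the test suite."""

import collections

import numpy as np

from devotf import clustering, cross_species


def truth_assignment(truth_table: dict) -> clustering.ClusterAssignment:
    """Hard assignment straight from simulation truth (archetype genes only)."""
    labels = {g: int(a) for g, a in truth_table.items() if a not in ("constant", "never")}
    return clustering.ClusterAssignment(labels, [], threshold=0.8)


def identity_pairing(k: int) -> cross_species.ClusterPairing:
    """Archetype i in species A paired with archetype i in species B."""
    return cross_species.ClusterPairing([(i, i, 0.0) for i in range(k)], [], [])


def dominant_archetype(assign: clustering.ClusterAssignment, truth_table: dict) -> dict:
    """Map each cluster to the truth archetype most of its members carry."""
    out = {}
    for cid in assign.clusters:
        counts = collections.Counter(truth_table[g] for g in assign.members_of(cid))
        out[cid] = counts.most_common(1)[0][0]
    return out


def archetype_recovery(result, pair) -> int:
    """Number of cluster pairs whose members agree on the truth archetype."""
    da = dominant_archetype(result.assign_a, pair.truth.archetype_of_a)
    db = dominant_archetype(result.assign_b, pair.truth.archetype_of_b)
    return sum(1 for i, j, _ in result.pairing.pairs if da.get(i) == db.get(j))


def hypergeom_pmf_table(N: int, K: int, n: int) -> dict[int, float]:
    """Exact hypergeometric pmf by binomial-coefficient enumeration."""
    from math import comb

    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    return {k: comb(K, k) * comb(N - K, n - k) / denom for k in range(lo, hi + 1)}
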