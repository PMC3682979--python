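"""End-to-end orchestration of the comparative analysis.

Runs the complete chain on a two-species dataset: filter and Z-normalize,
fuzzy c-means per species, cross-species cluster pairing, ortholog
concordance and correlation against their permutation nulls, the
time-point distance matrix, and family enrichment — and collects a single
JSON-serializable summary. Given a fixed seed the summary is byte-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, conservation, cross_species, hourglass
from .simulate import SimConfig, SimulatedPair, simulate_species_pair


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the serializable summary."""

    clustering_a: clustering.FuzzyClustering
    clustering_b: clustering.FuzzyClustering
    assign_a: clustering.ClusterAssignment
    assign_b: clustering.ClusterAssignment
    pairing: cross_species.ClusterPairing
    concordance: conservation.PermutationNullResult
    correlation: conservation.PermutationNullResult
    distance_matrix: hourglass.StageDistanceMatrix
    enrichment_a: pd.DataFrame
    enrichment_b: pd.DataFrame
    summary: dict

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_pipeline(
    pair: SimulatedPair,
    c: int = 7,
    m: float = 1.25,
    membership_threshold: float = 0.8,
    alpha_family: float = 0.0025,
    alpha_correlation: float = 0.05,
    n_sets: int = 1000,
    seed: int = 0,
) -> PipelineResult:
    """Run the full comparative analysis on a two-species dataset."""
    # per-species clustering
    filt_a = clustering.filter_for_clustering(pair.a.expression, pair.a.presence)
    filt_b = clustering.filter_for_clustering(pair.b.expression, pair.b.presence)
    za = clustering.z_normalize(filt_a)
    zb = clustering.z_normalize(filt_b)
    fc_a = clustering.fuzzy_cmeans(za, c=c, m=m, seed=seed)
    fc_b = clustering.fuzzy_cmeans(zb, c=c, m=m, seed=seed + 1)
    assign_a = clustering.assign_members(fc_a, membership_threshold)
    assign_b = clustering.assign_members(fc_b, membership_threshold)

    # cross-species pairing on the aligned grid
    ca, cb = aligned_centers(fc_a, za, fc_b, zb, pair.alignment)
    pairing = cross_species.pair_clusters(ca, cb)

    # conservation statistics
    conc = conservation.concordance_null(
        pair.orthologs, assign_a, assign_b, pairing, n_sets=n_sets, seed=seed + 2
    )
    al_idx = pair.alignment.indices(
        pair.a.expression.time_points, pair.b.expression.time_points
    )
    za_al = za.values.iloc[:, [i for i, _ in al_idx]]
    zb_al = zb.values.iloc[:, [j for _, j in al_idx]]
    n_sig, n_tested, _ = conservation.ortholog_correlations(
        pair.orthologs, za_al, zb_al, alpha=alpha_correlation
    )
    corr = conservation.correlation_null(
        pair.orthologs, za_al, zb_al, alpha=alpha_correlation,
        n_sets=n_sets, seed=seed + 3,
    )

    # hourglass distance field on the full grids
    dmat = hourglass.stage_distance_matrix(za, zb, pair.orthologs)
    profile_a = hourglass.min_distance_profile(dmat, "A")
    minima = hourglass.local_minima(profile_a["min_distance"].to_numpy())

    # family enrichment per species
    enr_a = clustering.cluster_family_enrichment(assign_a, pair.a.catalog, alpha_family)
    enr_b = clustering.cluster_family_enrichment(assign_b, pair.b.catalog, alpha_family)

    n_conc, n_elig = conservation.ortholog_cluster_concordance(
        pair.orthologs, assign_a, assign_b, pairing
    )
    summary = {
        "n_genes_clustered_a": int(za.values.shape[0]),
        "n_genes_clustered_b": int(zb.values.shape[0]),
        "n_assigned_a": len(assign_a),
        "n_assigned_b": len(assign_b),
        "n_cluster_pairs": len(pairing),
        "n_concordant": int(n_conc),
        "n_eligible": int(n_elig),
        "concordance_z": _round(conc.z_score),
        "concordance_empirical_p": _round(conc.empirical_p),
        "n_correlated": int(n_sig),
        "n_correlation_tested": int(n_tested),
        "correlation_z": _round(corr.z_score),
        "correlation_empirical_p": _round(corr.empirical_p),
        "hourglass_argmin_a": dmat.argmin[0],
        "hourglass_argmin_b": dmat.argmin[1],
        "hourglass_interior_minima": [int(i) for i, _ in minima["interior"]],
        "n_family_over_flags_a": int(enr_a["over"].sum()) if len(enr_a) else 0,
        "n_family_over_flags_b": int(enr_b["over"].sum()) if len(enr_b) else 0,
        "seed": seed,
    }
    return PipelineResult(
        clustering_a=fc_a, clustering_b=fc_b,
        assign_a=assign_a, assign_b=assign_b,
        pairing=pairing,
        concordance=conc, correlation=corr,
        distance_matrix=dmat,
        enrichment_a=enr_a, enrichment_b=enr_b,
        summary=summary,
    )


def run_default_simulation(seed: int = 0, config: SimConfig | None = None) -> PipelineResult:
    """Simulate the bundled two-species dataset and run the full pipeline."""
    pair = simulate_species_pair(config or SimConfig(), seed=seed)
    return run_pipeline(pair, seed=seed)


def aligned_centers(
    fc_a: clustering.FuzzyClustering,
    za,
    fc_b: clustering.FuzzyClustering,
    zb,
    alignment,
    restandardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centers restricted to the aligned time grid.

    By default each center row is re-standardized (mean 0, sd 1) over the
    common grid, so centers from species with different time grids (hence
    different per-species normalization constants) are compared by shape
    alone: two noiseless clusters of the same archetype then sit at
    distance 0.
    """
    ca, cb = cross_species.restrict_to_alignment(
        _centers_frame(fc_a, za), _centers_frame(fc_b, zb), alignment
    )
    if restandardize:
        ca = (ca - ca.mean(axis=1, keepdims=True)) / ca.std(axis=1, keepdims=True)
        cb = (cb - cb.mean(axis=1, keepdims=True)) / cb.std(axis=1, keepdims=True)
    return ca, cb


def _centers_frame(fc: clustering.FuzzyClustering, z) -> pd.DataFrame:
    from .containers import ExpressionTimeCourse

    df = pd.DataFrame(fc.centers, columns=z.values.columns)
    return ExpressionTimeCourse(z.species, df.rename(index=str))


def _round(x: float, digits: int = 10) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return round(float(x), digits)
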