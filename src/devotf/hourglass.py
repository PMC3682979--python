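"""Per-time-point transcriptome distance between species (hourglass analysis).

For every pair of time points (s in species A, t in species B) the Euclidean
distance between the vectors of Z-normalized ortholog expression is
computed; the minimum-distance profile along either axis locates the stage
of maximal cross-species similarity (the waist of the developmental
hourglass), and interior local minima flag secondary convergence periods.

Z-normalization here is per gene over that species' full time course — the
same standardization used for clustering — and the full |T_A| x |T_B|
matrix is computed, not just aligned time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse, OrthologMap


@dataclass
class StageDistanceMatrix:
    """All-pairs time-point distance between two species' TF transcriptomes."""

    species_a: str
    species_b: str
    distances: pd.DataFrame          # rows: A time points, cols: B time points
    n_orthologs: int
    ortholog_pairs: list[tuple[str, str]]

    @property
    def argmin(self) -> tuple[str, str]:
        d = self.distances.to_numpy()
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return str(self.distances.index[i]), str(self.distances.columns[j])

    @property
    def argmin_indices(self) -> tuple[int, int]:
        d = self.distances.to_numpy()
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return int(i), int(j)


def stage_distance_matrix(
    za: ExpressionTimeCourse | pd.DataFrame,
    zb: ExpressionTimeCourse | pd.DataFrame,
    om: OrthologMap,
) -> StageDistanceMatrix:
    """Euclidean distance between ortholog-expression vectors at all time pairs.

    ``za``/``zb`` are Z-normalized gene x time matrices (each gene
    standardized over its own species' full course). Only ortholog pairs
    with both genes present in the matrices contribute; fewer than 2 usable
    pairs is an error.
    """
    da = za.values if isinstance(za, ExpressionTimeCourse) else za
    db = zb.values if isinstance(zb, ExpressionTimeCourse) else zb
    sp_a = za.species if isinstance(za, ExpressionTimeCourse) else "A"
    sp_b = zb.species if isinstance(zb, ExpressionTimeCourse) else "B"
    usable = [(ga, gb) for ga, gb in om.pairs if ga in da.index and gb in db.index]
    if len(usable) < 2:
        raise ValueError(f"only {len(usable)} usable ortholog pairs (need >= 2)")
    A = da.loc[[ga for ga, _ in usable]].to_numpy(dtype=float)   # n_pairs x T_A
    B = db.loc[[gb for _, gb in usable]].to_numpy(dtype=float)   # n_pairs x T_B
    # rows of A.T / B.T are per-time-point ortholog-expression vectors
    from scipy.spatial.distance import cdist

    d = cdist(A.T, B.T)
    return StageDistanceMatrix(
        species_a=sp_a,
        species_b=sp_b,
        distances=pd.DataFrame(d, index=da.columns, columns=db.columns),
        n_orthologs=len(usable),
        ortholog_pairs=usable,
    )


def min_distance_profile(D: StageDistanceMatrix, axis: str = "A") -> pd.DataFrame:
    """Minimum distance from each time point of one species to any of the other.

    ``axis="A"`` gives, for each A time point, the smallest distance over all
    B time points (and the B time point attaining it); ``axis="B"`` the
    converse.
    """
    d = D.distances
    if axis == "A":
        mins = d.min(axis=1)
        arg = d.idxmin(axis=1)
        return pd.DataFrame({"time": d.index, "min_distance": mins.values,
                             "closest": arg.values})
    if axis == "B":
        mins = d.min(axis=0)
        arg = d.idxmin(axis=0)
        return pd.DataFrame({"time": d.columns, "min_distance": mins.values,
                             "closest": arg.values})
    raise ValueError("axis must be 'A' or 'B'")


def local_minima(profile: np.ndarray | pd.Series) -> dict[str, list[tuple[int, float]]]:
    """Strict interior local minima of a distance profile.

    A position i (0 < i < len-1) is an interior minimum when
    profile[i] < profile[i-1] and profile[i] < profile[i+1]. Boundary
    positions that undercut their single neighbour are reported separately.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        raise ValueError("profile too short for minima detection")
    interior = [
        (i, float(p[i]))
        for i in range(1, p.size - 1)
        if p[i] < p[i - 1] and p[i] < p[i + 1]
    ]
    boundary = []
    if p[0] < p[1]:
        boundary.append((0, float(p[0])))
    if p[-1] < p[-2]:
        boundary.append((p.size - 1, float(p[-1])))
    return {"interior": interior, "boundary": boundary}
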