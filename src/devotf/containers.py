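"""Core in-memory containers for the comparative TF-expression pipeline.

Expression matrices are pandas DataFrames (genes x ordered time points);
the thin dataclass wrappers pin the invariants the downstream stages rely
on (unique gene ids, no missing values, ordered time labels) and carry the
species identity and provenance metadata alongside the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A pipeline input file violated its schema (carries the line number)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


#: The six structural families the comparative analysis focuses on; other
#: family labels from domain-assignment files are kept verbatim.
CANONICAL_FAMILIES = ("Homeobox", "zf-C2H2", "zf-C4", "Ets", "bZIP", "HLH")


@dataclass
class TFCatalog:
    """Transcription-factor catalog: gene id -> set of DNA-binding-domain families.

    Genes with several domain types carry every family label (the underlying
    domain-assignment lists are many-to-many).
    """

    species: str
    assignments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, fams in self.assignments.items():
            if not fams:
                raise ValueError(f"gene {gene!r} has no family label")
            if not isinstance(fams, frozenset):
                self.assignments[gene] = frozenset(fams)

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)

    @property
    def families(self) -> list[str]:
        out: set[str] = set()
        for fams in self.assignments.values():
            out.update(fams)
        return sorted(out)

    def members_of(self, family: str) -> list[str]:
        return [g for g, fams in self.assignments.items() if family in fams]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class ExpressionTimeCourse:
    """Gene x time-point matrix of log2 expression for one species.

    ``values`` rows are genes, columns are ordered time-point labels.
    ``time_hours`` gives each column a numeric time when the labels parse as
    numbers (used for plotting and warp alignment); otherwise it is None.
    """

    species: str
    values: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate time-point labels")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_points(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def time_hours(self) -> np.ndarray | None:
        try:
            return np.array([float(c) for c in self.values.columns])
        except (TypeError, ValueError):
            return None

    @property
    def n_time_points(self) -> int:
        return self.values.shape[1]

    def subset(self, genes: Iterable[str]) -> "ExpressionTimeCourse":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionTimeCourse(self.species, self.values.loc[genes], dict(self.meta))


@dataclass
class ProbeTable:
    """Probe-level matrix before gene summarization.

    Columns encode (time point, replicate); ``sample_info`` maps each column
    label to that pair. Probes without a gene mapping are legal — they are
    dropped (and counted) at collapse time.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str]
    sample_info: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.sample_info]
        if missing:
            raise ValueError(f"columns without (time, replicate) mapping: {missing[:5]}")

    @property
    def time_labels(self) -> list[str]:
        """Time labels in first-appearance column order."""
        seen: list[str] = []
        for c in self.values.columns:
            t = self.sample_info[c][0]
            if t not in seen:
                seen.append(t)
        return seen

    def columns_for(self, time_label: str) -> list[str]:
        return [c for c in self.values.columns if self.sample_info[c][0] == time_label]


@dataclass
class PresenceTable:
    """Gene x time-point boolean expressed/not-expressed calls."""

    species: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(bool)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in presence table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_points(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def ever_present(self) -> pd.Series:
        return self.values.any(axis=1)


@dataclass
class OrthologMap:
    """Unique seed-ortholog pairs between two species."""

    species_a: str
    species_b: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError("ortholog pair with empty gene id")
        seen = set()
        deduped = []
        for p in self.pairs:
            if p not in seen:
                seen.add(p)
                deduped.append(p)
        self.n_duplicates_dropped = len(self.pairs) - len(deduped)
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TimeAlignment:
    """Monotone correspondence between two species' time points.

    Stored as (label_a, label_b) pairs in course order; ``indices`` resolves
    them against two time courses and enforces strict monotonicity in both
    coordinates.
    """

    species_a: str
    species_b: str
    label_pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.label_pairs)

    def indices(
        self, time_points_a: Sequence[str], time_points_b: Sequence[str]
    ) -> list[tuple[int, int]]:
        pos_a = {str(t): i for i, t in enumerate(time_points_a)}
        pos_b = {str(t): i for i, t in enumerate(time_points_b)}
        out: list[tuple[int, int]] = []
        for la, lb in self.label_pairs:
            if la not in pos_a:
                raise ValueError(f"alignment label {la!r} not a time point of {self.species_a}")
            if lb not in pos_b:
                raise ValueError(f"alignment label {lb!r} not a time point of {self.species_b}")
            out.append((pos_a[la], pos_b[lb]))
        _check_monotone(out)
        return out


def _check_monotone(pairs: Sequence[tuple[int, int]]) -> None:
    for (a0, b0), (a1, b1) in zip(pairs, pairs[1:]):
        if not (a1 > a0 and b1 > b0):
            raise ValueError(
                f"alignment not strictly increasing at ({a0},{b0}) -> ({a1},{b1})"
            )
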