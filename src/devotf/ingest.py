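"""File formats, preprocessing and presence calling.

Readers are strict: malformed rows raise :class:`~devotf.containers.ParseError`
with a line number rather than being silently coerced. Writers round-trip with
the readers.

Formats
-------
* TF domain assignments: tab-delimited ``gene_id<TAB>family``, ``#`` comments
  (the DBD ``*.tf.ass`` dialect).
* Expression / presence tables: TSV, first column ``gene_id``, one column per
  time point, header row carries the time labels. Presence tables hold 0/1.
* Probe tables: TSV with ``probe_id``, ``gene_id`` columns followed by sample
  columns headed ``T<label>_r<k>``.
* Ortholog tables: TSV ``gene_a<TAB>gene_b``.
* Alignment tables: TSV ``time_label_a<TAB>time_label_b``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionTimeCourse,
    OrthologMap,
    ParseError,
    PresenceTable,
    ProbeTable,
    TFCatalog,
    TimeAlignment,
)

log = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^T(?P<time>.+)_r(?P<rep>\d+)$")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _two_column_rows(path: str | Path) -> list[tuple[int, str, str]]:
    rows: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"expected 2 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            rows.append((lineno, fields[0].strip(), fields[1].strip()))
    return rows


def read_tf_assignments(path: str | Path, species: str | None = None) -> TFCatalog:
    """Read a DBD-style domain-assignment file into a :class:`TFCatalog`.

    One row per (gene, family) assignment; multi-domain genes accumulate all
    their family labels; duplicate rows collapse under set semantics.
    """
    rows = _two_column_rows(path)
    if not rows:
        raise ParseError("no assignments", str(path))
    assignments: dict[str, set[str]] = {}
    for _, gene, family in rows:
        assignments.setdefault(gene, set()).add(family)
    if species is None:
        species = Path(path).stem.split(".")[0]
    return TFCatalog(species, {g: frozenset(f) for g, f in assignments.items()})


def write_tf_assignments(cat: TFCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# TF domain assignments for {cat.species}\n")
        for gene in cat.assignments:
            for fam in sorted(cat.assignments[gene]):
                fh.write(f"{gene}\t{fam}\n")


def read_expression_table(path: str | Path, species: str | None = None) -> ExpressionTimeCourse:
    """Read a gene x time-point TSV of expression values."""
    df = _read_matrix(path)
    if species is None:
        species = Path(path).stem.split(".")[0]
    return ExpressionTimeCourse(species, df)


def write_expression_table(x: ExpressionTimeCourse, path: str | Path) -> None:
    x.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_presence_table(path: str | Path, species: str | None = None) -> PresenceTable:
    df = _read_matrix(path)
    bad = ~df.isin([0, 1, 0.0, 1.0]).all(axis=None)
    if bad:
        raise ParseError("presence table entries must be 0 or 1", str(path))
    if species is None:
        species = Path(path).stem.split(".")[0]
    return PresenceTable(species, df.astype(bool))


def write_presence_table(p: PresenceTable, path: str | Path) -> None:
    p.values.astype(int).rename_axis("gene_id").to_csv(path, sep="\t")


def _read_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse table: {exc}", str(path)) from exc
    if df.shape[1] == 0:
        raise ParseError("table has no time-point columns", str(path))
    df.columns = [str(c) for c in df.columns]
    df.index = df.index.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy())) + 2  # +1 header, +1 1-based
            raise ParseError(f"non-numeric value in column {col!r}", str(path), row)
        df[col] = vals
    return df


def read_probe_table(path: str | Path) -> ProbeTable:
    """Read a probe-level table; sample columns are headed ``T<label>_r<k>``."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    except Exception as exc:
        raise ParseError(f"cannot parse probe table: {exc}", str(path)) from exc
    if "probe_id" not in df.columns or "gene_id" not in df.columns:
        raise ParseError("probe table needs probe_id and gene_id columns", str(path))
    sample_cols = [c for c in df.columns if c not in ("probe_id", "gene_id")]
    sample_info: dict[str, tuple[str, int]] = {}
    for c in sample_cols:
        m = _SAMPLE_RE.match(c)
        if m is None:
            raise ParseError(f"sample column {c!r} not of form T<label>_r<k>", str(path))
        sample_info[c] = (m.group("time"), int(m.group("rep")))
    values = df.set_index("probe_id")[sample_cols].astype(float)
    probe_to_gene = {
        p: g for p, g in zip(df["probe_id"], df["gene_id"]) if g and g != "-"
    }
    return ProbeTable(values, probe_to_gene, sample_info)


def write_probe_table(t: ProbeTable, path: str | Path) -> None:
    df = t.values.copy()
    df.insert(0, "gene_id", [t.probe_to_gene.get(p, "-") for p in df.index])
    df.rename_axis("probe_id").to_csv(path, sep="\t", float_format="%.6g")


def read_ortholog_table(
    path: str | Path, species_a: str = "A", species_b: str = "B"
) -> OrthologMap:
    """Read seed-ortholog pairs; duplicates are dropped and logged."""
    rows = _two_column_rows(path)
    om = OrthologMap(species_a, species_b, [(a, b) for _, a, b in rows])
    if om.n_duplicates_dropped:
        log.info("dropped %d duplicate ortholog pairs", om.n_duplicates_dropped)
    return om


def write_ortholog_table(om: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# orthologs {om.species_a} vs {om.species_b}\n")
        for a, b in om.pairs:
            fh.write(f"{a}\t{b}\n")


def read_alignment(
    path: str | Path, species_a: str = "A", species_b: str = "B"
) -> TimeAlignment:
    """Read a time-point alignment table.

    When both label columns parse as numbers the strict-monotonicity
    invariant is enforced immediately; otherwise it is enforced when the
    alignment is resolved against the two time courses.
    """
    rows = _two_column_rows(path)
    if not rows:
        raise ParseError("empty alignment", str(path))
    pairs = [(a, b) for _, a, b in rows]
    try:
        hours = [(float(a), float(b)) for a, b in pairs]
    except ValueError:
        hours = None
    if hours is not None:
        for (a0, b0), (a1, b1) in zip(hours, hours[1:]):
            if not (a1 > a0 and b1 > b0):
                raise ParseError(
                    f"alignment not strictly increasing at ({a0},{b0}) -> ({a1},{b1})",
                    str(path),
                )
    return TimeAlignment(species_a, species_b, pairs)


def write_alignment(al: TimeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# time alignment {al.species_a} vs {al.species_b}\n")
        for a, b in al.label_pairs:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Between-column quantile normalization.

    Every column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the mean of the reference
    values over their rank span, so equal inputs map to equal outputs.
    """
    df = isinstance(values, pd.DataFrame)
    x = values.to_numpy(dtype=float) if df else np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed in quantile normalization")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        out[order, j] = reference
        # ties: average the reference values across each tied run
        sorted_col = col[order]
        i = 0
        n = len(col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                out[order[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    if df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_probes(t: ProbeTable, species: str = "species") -> ExpressionTimeCourse:
    """Average probe-level values to one expression value per gene per time point.

    The mean runs over every probe mapped to the gene and every replicate of
    the time point; probes without a gene mapping are dropped and counted.
    """
    mapped = [p for p in t.values.index if p in t.probe_to_gene]
    n_dropped = len(t.values.index) - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    genes = sorted({t.probe_to_gene[p] for p in mapped})
    times = t.time_labels
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=times, dtype=float)
    by_gene: dict[str, list[str]] = {}
    for p in mapped:
        by_gene.setdefault(t.probe_to_gene[p], []).append(p)
    for g, probes in by_gene.items():
        for tl in times:
            cols = t.columns_for(tl)
            out.loc[g, tl] = float(t.values.loc[probes, cols].to_numpy().mean())
    x = ExpressionTimeCourse(species, out)
    x.meta["n_unmapped_probes_dropped"] = n_dropped
    return x


def log_transform_fpkm(
    fpkm: pd.DataFrame, pseudocount: float = 0.01, species: str = "species"
) -> ExpressionTimeCourse:
    """log2(FPKM + pseudocount) expression values.

    The pseudocount keeps zero-FPKM genes finite and far below the
    constant-expression filter; it must be strictly positive and is recorded
    in the provenance metadata.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    vals = fpkm.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("FPKM values must be non-negative")
    out = pd.DataFrame(np.log2(vals + pseudocount), index=fpkm.index, columns=fpkm.columns)
    x = ExpressionTimeCourse(species, out)
    x.meta["pseudocount"] = pseudocount
    x.meta["transform"] = "log2(fpkm + pseudocount)"
    return x


# ---------------------------------------------------------------------------
# presence calling
# ---------------------------------------------------------------------------

def call_presence_flags(flags: ProbeTable, species: str = "species") -> PresenceTable:
    """AND-rule detection calls from probe-level detection flags.

    A gene is present at a time point only if every probe of that gene in
    every replicate of that time point is flagged detected. Genes with zero
    mapped probes never appear; they are warned about.
    """
    mapped = [p for p in flags.values.index if p in flags.probe_to_gene]
    genes = sorted({flags.probe_to_gene[p] for p in mapped})
    unmapped = set(flags.values.index) - set(mapped)
    if unmapped:
        log.warning("call_presence_flags: %d probes without gene mapping", len(unmapped))
    times = flags.time_labels
    by_gene: dict[str, list[str]] = {}
    for p in mapped:
        by_gene.setdefault(flags.probe_to_gene[p], []).append(p)
    out = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"), columns=times)
    fv = flags.values.astype(bool)
    for g, probes in by_gene.items():
        for tl in times:
            cols = flags.columns_for(tl)
            out.loc[g, tl] = bool(fv.loc[probes, cols].to_numpy().all())
    return PresenceTable(species, out)


def call_presence_fpkm(
    fpkm: pd.DataFrame, threshold: float = 1.0, species: str = "species"
) -> PresenceTable:
    """Present iff FPKM strictly exceeds the threshold (default 1)."""
    vals = fpkm.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return PresenceTable(
        species, pd.DataFrame(vals > threshold, index=fpkm.index, columns=fpkm.columns)
    )


def call_presence_floor(
    x: ExpressionTimeCourse, floor: float
) -> PresenceTable:
    """Present iff log2 expression strictly exceeds ``floor``."""
    return PresenceTable(x.species, x.values > floor)
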