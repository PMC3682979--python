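"""Synthetic two-species developmental time courses with known ground truth.

The generator emulates the inputs of the comparative pipeline: two species
share a bank of temporal archetypes (maternal decay, activated-sustained,
activated-transient, late rise, ...) expressed on species-specific time
grids related by a piecewise-linear warp. Gene-level log2 expression is the
archetype curve scaled into realistic units plus i.i.d. Gaussian noise;
planted classes of never-expressed and constant genes exercise the
clustering filters; ortholog pairs share their archetype with a configured
concordance fraction; TF-family labels carry a planted family-by-archetype
enrichment; and a configurable convergence window modulates cross-species
divergence so the time-point distance matrix has an hourglass waist.

Everything is deterministic given (config, seed), and datasets round-trip
through the ingest readers/writers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest
from .containers import (
    ExpressionTimeCourse,
    OrthologMap,
    PresenceTable,
    ProbeTable,
    TFCatalog,
    TimeAlignment,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default time grids: species A mirrors a 12-point course over one day
#: (interval midpoints), species B a 14-point course over ~2 days of which
#: 12 points are manually aligned to A's grid.
_A_HOURS = tuple(float(h) for h in range(1, 24, 2))
_B_HOURS = (2.0, 4.0, 6.0, 10.0, 16.0, 19.0, 22.0, 28.5, 31.0, 34.0, 40.0, 43.0, 46.0, 49.0)
_B_ALIGNED = (2.0, 6.0, 10.0, 16.0, 19.0, 22.0, 28.5, 31.0, 34.0, 40.0, 43.0, 49.0)

_DEFAULT_FAMILY_FREQS = {
    "zf-C2H2": 0.25,
    "Homeobox": 0.20,
    "HLH": 0.08,
    "bZIP": 0.06,
    "zf-C4": 0.05,
    "Ets": 0.04,
    "other": 0.32,
}


@dataclass
class SimConfig:
    """Study conditions for the two-species simulation.

    Defaults follow the scale of the real comparisons: ~700 TFs per species,
    7 temporal archetypes, log2-scale Gaussian noise of sd 0.3, 10% constant
    and 5% never-expressed genes, 300 ortholog pairs of which half share
    their archetype, and a mid-development convergence window.
    """

    n_genes: int = 700
    n_archetypes: int = 7
    noise_sd: float = 0.3
    frac_never_expressed: float = 0.05
    frac_constant: float = 0.10
    n_orthologs: int = 300
    concordance: float = 0.5

    # expression scale (log2 units)
    baseline: float = 6.0
    amplitude: float = 2.5
    amplitude_jitter: tuple[float, float] = (0.8, 1.2)
    presence_floor: float = 4.0
    never_expressed_level: float = -2.0
    constant_jitter: float = 0.2

    # time grids and warp (hours); alignment pairs are (hour_a, hour_b)
    time_hours_a: tuple[float, ...] = _A_HOURS
    time_hours_b: tuple[float, ...] = _B_HOURS
    alignment_hours: tuple[tuple[float, float], ...] = tuple(
        zip(_A_HOURS, _B_ALIGNED)
    )

    # family labels and planted enrichment
    family_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_FAMILY_FREQS))
    second_family_prob: float = 0.05
    enriched_family: str = "zf-C2H2"
    enriched_archetype: int = 0
    enrichment_odds: float = 5.0

    # hourglass geometry: windows in developmental-progress units [0, 1];
    # species divergence noise (applied to ortholog genes) has sd 0 inside a
    # window, ramping linearly to divergence_scale over divergence_ramp
    # progress units outside it
    hourglass_windows: tuple[tuple[float, float], ...] = ((0.40, 0.60),)
    divergence_scale: float = 1.0
    divergence_ramp: float = 0.15

    species_a: str = "speciesA"
    species_b: str = "speciesB"

    def __post_init__(self) -> None:
        if not (0.0 <= self.concordance <= 1.0):
            raise ValueError("concordance fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.frac_never_expressed + self.frac_constant >= 1.0:
            raise ValueError("planted never/constant fractions leave no archetype genes")
        if self.n_archetypes < 2:
            raise ValueError("need at least 2 archetypes")
        freq_total = sum(self.family_freqs.values())
        if not np.isclose(freq_total, 1.0, atol=1e-6):
            raise ValueError(f"family frequencies sum to {freq_total}, expected 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("time_hours_a", "time_hours_b", "amplitude_jitter"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "alignment_hours" in raw:
            raw["alignment_hours"] = tuple(tuple(p) for p in raw["alignment_hours"])
        if "hourglass_windows" in raw:
            raw["hourglass_windows"] = tuple(tuple(w) for w in raw["hourglass_windows"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fmt_hour(h: float) -> str:
    return f"{h:g}"


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeSet:
    """Unit-variance temporal shapes on a common grid, with their callables."""

    curves: np.ndarray                 # k x T, each row mean 0 sd 1
    labels: list[str]
    functions: list = field(repr=False, default_factory=list)

    @property
    def k(self) -> int:
        return self.curves.shape[0]

    def min_pairwise_distance(self) -> float:
        k = self.k
        dmin = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                dmin = min(dmin, float(np.linalg.norm(self.curves[i] - self.curves[j])))
        return dmin


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _shape_bank(k: int, rng: np.random.Generator) -> list[tuple[str, callable]]:
    """k named temporal shape functions of progress s in [0, 1].

    The first three guarantee one monotone-decreasing (maternal), one
    sigmoidal increase (activated) and one unimodal (transient) shape;
    midpoints get a small seeded jitter so distinct seeds give distinct but
    equally well-separated banks.
    """
    j = lambda: float(rng.uniform(-0.02, 0.02))
    bank: list[tuple[str, callable]] = [
        ("maternal-decay",
         (lambda m: (lambda s: 1.0 - _sigmoid((s - m) / 0.08)))(0.25 + j())),
        ("activated-sustained",
         (lambda m: (lambda s: _sigmoid((s - m) / 0.08)))(0.35 + j())),
        ("activated-transient",
         (lambda m: (lambda s: np.exp(-(((s - m) / 0.12) ** 2))))(0.45 + j())),
        ("maternal-slow-decay",
         (lambda m: (lambda s: -(s - m)))(0.0 + j())),
        ("late-rise",
         (lambda m: (lambda s: _sigmoid((s - m) / 0.06)))(0.72 + j())),
        ("late-transient",
         (lambda m: (lambda s: np.exp(-(((s - m) / 0.10) ** 2))))(0.75 + j())),
        ("early-transient",
         (lambda m: (lambda s: np.exp(-(((s - m) / 0.10) ** 2))))(0.18 + j())),
    ]
    extra = 0
    while len(bank) < k:
        m = 0.1 + 0.8 * (extra + 0.5) / max(1, k - 7)
        width = 0.06 + 0.02 * (extra % 3)
        bank.append(
            (f"transient-{extra}",
             (lambda mm, ww: (lambda s: np.exp(-(((s - mm) / ww) ** 2))))(m + j(), width))
        )
        extra += 1
    return bank[:k]


def _znorm_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("degenerate archetype shape (zero variance on grid)")
    return (x - mean) / sd


def make_archetypes(k: int, T: int, seed: int) -> ArchetypeSet:
    """Build k unit-variance archetype curves on a uniform T-point grid.

    Deterministic given the seed; for k >= 3 the bank always includes a
    monotone-decreasing maternal shape, a sigmoidal activation and a
    unimodal transient.
    """
    if k < 2:
        raise ValueError("need k >= 2 archetypes")
    if T < 4:
        raise ValueError("need T >= 4 time points")
    if k > T:
        raise ValueError(f"k={k} archetypes undersampled on T={T} points")
    rng = np.random.default_rng(seed)
    bank = _shape_bank(k, rng)
    grid = np.linspace(0.0, 1.0, T)
    curves = _znorm_rows(np.vstack([fn(grid) for _, fn in bank]))
    return ArchetypeSet(curves, [name for name, _ in bank], [fn for _, fn in bank])


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth for one simulated species pair."""

    archetype_of_a: dict[str, str]     # gene -> archetype index (str) / "constant" / "never"
    archetype_of_b: dict[str, str]
    ortholog_pairs: list[tuple[str, str, bool]]   # (gene_a, gene_b, concordant flag)
    archetype_labels: list[str]
    enriched_family: str
    enriched_archetype: int
    enrichment_odds: float
    hourglass_windows: list[tuple[float, float]]
    warp_hours: list[tuple[float, float]]         # (hour_a, hour_b) anchors
    config: dict = field(default_factory=dict)

    @property
    def concordant_fraction(self) -> float:
        if not self.ortholog_pairs:
            return float("nan")
        return sum(1 for *_, c in self.ortholog_pairs if c) / len(self.ortholog_pairs)

    def labels_for(self, species: str, genes) -> list[str]:
        table = self.archetype_of_a if species == "a" else self.archetype_of_b
        return [table[g] for g in genes]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "archetype_of_a": self.archetype_of_a,
            "archetype_of_b": self.archetype_of_b,
            "ortholog_pairs": [[a, b, bool(c)] for a, b, c in self.ortholog_pairs],
            "archetype_labels": self.archetype_labels,
            "enriched_family": self.enriched_family,
            "enriched_archetype": self.enriched_archetype,
            "enrichment_odds": self.enrichment_odds,
            "hourglass_windows": [list(w) for w in self.hourglass_windows],
            "warp_hours": [list(w) for w in self.warp_hours],
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            archetype_of_a=raw["archetype_of_a"],
            archetype_of_b=raw["archetype_of_b"],
            ortholog_pairs=[(a, b, bool(c)) for a, b, c in raw["ortholog_pairs"]],
            archetype_labels=raw["archetype_labels"],
            enriched_family=raw["enriched_family"],
            enriched_archetype=raw["enriched_archetype"],
            enrichment_odds=raw["enrichment_odds"],
            hourglass_windows=[tuple(w) for w in raw["hourglass_windows"]],
            warp_hours=[tuple(w) for w in raw["warp_hours"]],
            config=raw.get("config", {}),
        )


@dataclass
class SpeciesDataset:
    """One simulated species: expression, presence calls and TF catalog."""

    expression: ExpressionTimeCourse
    presence: PresenceTable
    catalog: TFCatalog


@dataclass
class SimulatedPair:
    """Complete simulated input set for the cross-species pipeline."""

    a: SpeciesDataset
    b: SpeciesDataset
    orthologs: OrthologMap
    alignment: TimeAlignment
    truth: SyntheticTruth
    archetypes_a: ArchetypeSet | None = None
    archetypes_b: ArchetypeSet | None = None


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

def _progress_a(cfg: SimConfig) -> np.ndarray:
    h = np.asarray(cfg.time_hours_a, dtype=float)
    return (h - h[0]) / (h[-1] - h[0])


def _progress_b(cfg: SimConfig) -> np.ndarray:
    """Map species-B hours onto species-A developmental progress via the
    piecewise-linear warp through the alignment anchors."""
    anchors_a = np.array([a for a, _ in cfg.alignment_hours], dtype=float)
    anchors_b = np.array([b for _, b in cfg.alignment_hours], dtype=float)
    if not (np.all(np.diff(anchors_a) > 0) and np.all(np.diff(anchors_b) > 0)):
        raise ValueError("warp anchors must be strictly increasing")
    hb = np.asarray(cfg.time_hours_b, dtype=float)
    equiv_a = np.interp(hb, anchors_b, anchors_a)
    ha = np.asarray(cfg.time_hours_a, dtype=float)
    return (equiv_a - ha[0]) / (ha[-1] - ha[0])


def _window_weight(progress: np.ndarray, windows, ramp: float) -> np.ndarray:
    """Divergence weight in [0, 1]: 0 inside any window, ramping linearly to
    1 over ``ramp`` progress units of distance to the nearest window."""
    if not windows:
        return np.zeros_like(progress)
    dist = np.full_like(progress, np.inf)
    for lo, hi in windows:
        d = np.where(
            progress < lo, lo - progress, np.where(progress > hi, progress - hi, 0.0)
        )
        dist = np.minimum(dist, d)
    if ramp <= 0:
        return (dist > 0).astype(float)
    return np.minimum(dist / ramp, 1.0)


def _sample_families(
    cfg: SimConfig, archetype: list[str], rng: np.random.Generator
) -> dict[str, frozenset[str]]:
    fams = list(cfg.family_freqs)
    base = np.array([cfg.family_freqs[f] for f in fams], dtype=float)
    out: dict[str, frozenset[str]] = {}
    enriched_idx = fams.index(cfg.enriched_family) if cfg.enriched_family in fams else None
    for gene, arch in archetype:
        w = base.copy()
        if enriched_idx is not None and arch == str(cfg.enriched_archetype):
            w[enriched_idx] *= cfg.enrichment_odds
        w /= w.sum()
        primary = fams[rng.choice(len(fams), p=w)]
        labels = {primary}
        if rng.random() < cfg.second_family_prob:
            labels.add(fams[rng.choice(len(fams), p=base / base.sum())])
        out[gene] = frozenset(labels)
    return out


def _simulate_species(
    cfg: SimConfig,
    species: str,
    prefix: str,
    progress: np.ndarray,
    time_labels: list[str],
    archetype_of: list[str],
    functions: list,
    divergent: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ExpressionTimeCourse, PresenceTable, np.ndarray]:
    """Expression matrix for one species given per-gene archetype labels.

    ``divergent`` marks genes receiving extra hourglass divergence noise
    (sd = divergence_scale * window weight) — the ortholog genes.
    """
    n = len(archetype_of)
    T = len(progress)
    curves = _znorm_rows(np.vstack([fn(progress) for fn in functions]))
    w = _window_weight(progress, cfg.hourglass_windows, cfg.divergence_ramp)
    vals = np.empty((n, T))
    for i, arch in enumerate(archetype_of):
        if arch == "never":
            vals[i] = cfg.never_expressed_level + rng.uniform(
                -cfg.constant_jitter, cfg.constant_jitter, size=T
            )
        elif arch == "constant":
            vals[i] = cfg.baseline + rng.uniform(
                -cfg.constant_jitter, cfg.constant_jitter, size=T
            )
        else:
            amp = cfg.amplitude * rng.uniform(*cfg.amplitude_jitter)
            base = cfg.baseline + rng.normal(0.0, 0.5)
            vals[i] = base + amp * curves[int(arch)] + rng.normal(0.0, cfg.noise_sd, size=T)
            if divergent[i] and cfg.divergence_scale > 0:
                vals[i] += rng.normal(0.0, 1.0, size=T) * (cfg.divergence_scale * w)
    genes = [f"{prefix}_g{i:04d}" for i in range(n)]
    df = pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"), columns=time_labels)
    expr = ExpressionTimeCourse(species, df, {"simulated": True})
    presence = PresenceTable(species, df > cfg.presence_floor)
    return expr, presence, curves


def simulate_species_pair(
    config: SimConfig | None = None, seed: int = 0
) -> SimulatedPair:
    """Simulate the full two-species input set with ground truth.

    Gene classes are assigned deterministically by count (never-expressed,
    constant, archetype); ortholog pairs are drawn among archetype genes
    with exactly ``round(concordance * n_orthologs)`` concordant pairs
    sharing their archetype, the rest drawing independently.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, k = cfg.n_genes, cfg.n_archetypes
    n_never = int(round(cfg.frac_never_expressed * n))
    n_const = int(round(cfg.frac_constant * n))
    n_arch = n - n_never - n_const
    if cfg.n_orthologs > n_arch:
        raise ValueError("more ortholog pairs requested than archetype genes")

    def assign_classes(rng_: np.random.Generator) -> list[str]:
        labels = (
            [str(int(a)) for a in rng_.integers(0, k, size=n_arch)]
            + ["constant"] * n_const
            + ["never"] * n_never
        )
        return labels

    arch_a = assign_classes(rng)
    arch_b = assign_classes(rng)

    # ortholog pairs among archetype genes (indices < n_arch on both sides)
    idx_a = rng.choice(n_arch, size=cfg.n_orthologs, replace=False)
    idx_b = rng.choice(n_arch, size=cfg.n_orthologs, replace=False)
    n_conc = int(round(cfg.concordance * cfg.n_orthologs))
    concordant = np.zeros(cfg.n_orthologs, dtype=bool)
    concordant[:n_conc] = True
    for t, (ia, ib) in enumerate(zip(idx_a, idx_b)):
        if concordant[t]:
            arch_b[ib] = arch_a[ia]

    # the convergence window modulates how tightly concordant pairs share
    # shapes: their genes receive divergence noise that vanishes inside the
    # window; discordant pairs are independent everywhere already
    divergent_a = np.zeros(n, dtype=bool)
    divergent_a[idx_a[concordant]] = True
    divergent_b = np.zeros(n, dtype=bool)
    divergent_b[idx_b[concordant]] = True

    labels_a = [_fmt_hour(h) for h in cfg.time_hours_a]
    labels_b = [_fmt_hour(h) for h in cfg.time_hours_b]
    prog_a = _progress_a(cfg)
    prog_b = _progress_b(cfg)

    bank = _shape_bank(k, np.random.default_rng(np.random.SeedSequence([seed, 7])))
    functions = [fn for _, fn in bank]
    shape_labels = [name for name, _ in bank]

    expr_a, pres_a, curves_a = _simulate_species(
        cfg, cfg.species_a, "ga", prog_a, labels_a, arch_a, functions, divergent_a, rng
    )
    expr_b, pres_b, curves_b = _simulate_species(
        cfg, cfg.species_b, "gb", prog_b, labels_b, arch_b, functions, divergent_b, rng
    )

    genes_a, genes_b = expr_a.genes, expr_b.genes
    catalog_a = TFCatalog(
        cfg.species_a, _sample_families(cfg, list(zip(genes_a, arch_a)), rng)
    )
    catalog_b = TFCatalog(
        cfg.species_b, _sample_families(cfg, list(zip(genes_b, arch_b)), rng)
    )

    pairs = [
        (genes_a[ia], genes_b[ib], bool(c))
        for ia, ib, c in zip(idx_a, idx_b, concordant)
    ]
    om = OrthologMap(cfg.species_a, cfg.species_b, [(a, b) for a, b, _ in pairs])
    alignment = TimeAlignment(
        cfg.species_a,
        cfg.species_b,
        [(_fmt_hour(a), _fmt_hour(b)) for a, b in cfg.alignment_hours],
    )
    truth = SyntheticTruth(
        archetype_of_a=dict(zip(genes_a, arch_a)),
        archetype_of_b=dict(zip(genes_b, arch_b)),
        ortholog_pairs=pairs,
        archetype_labels=shape_labels,
        enriched_family=cfg.enriched_family,
        enriched_archetype=cfg.enriched_archetype,
        enrichment_odds=cfg.enrichment_odds,
        hourglass_windows=[tuple(w) for w in cfg.hourglass_windows],
        warp_hours=[tuple(p) for p in cfg.alignment_hours],
        config=cfg.to_dict(),
    )
    return SimulatedPair(
        a=SpeciesDataset(expr_a, pres_a, catalog_a),
        b=SpeciesDataset(expr_b, pres_b, catalog_b),
        orthologs=om,
        alignment=alignment,
        truth=truth,
        archetypes_a=ArchetypeSet(curves_a, shape_labels, functions),
        archetypes_b=ArchetypeSet(curves_b, shape_labels, functions),
    )


# ---------------------------------------------------------------------------
# optional auxiliary inputs
# ---------------------------------------------------------------------------

def make_probe_table(
    x: ExpressionTimeCourse,
    n_probes: int = 2,
    n_replicates: int = 2,
    probe_noise_sd: float = 0.1,
    seed: int = 0,
) -> ProbeTable:
    """Expand a gene-level time course into a noisy probe x sample table."""
    rng = np.random.default_rng(seed)
    probes, rows = [], []
    sample_cols = [
        f"T{t}_r{r + 1}" for t in x.time_points for r in range(n_replicates)
    ]
    probe_to_gene = {}
    for g in x.genes:
        base = x.values.loc[g].to_numpy()
        for p in range(n_probes):
            pid = f"{g}_p{p + 1}"
            probes.append(pid)
            probe_to_gene[pid] = g
            vals = np.repeat(base, n_replicates) + rng.normal(
                0.0, probe_noise_sd, size=base.size * n_replicates
            )
            rows.append(vals)
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probes, name="probe_id"), columns=sample_cols
    )
    sample_info = {
        c: (c[1 : c.rfind("_r")], int(c[c.rfind("_r") + 2 :])) for c in sample_cols
    }
    return ProbeTable(values, probe_to_gene, sample_info)


def make_ontology(
    truth: SyntheticTruth,
    species: str = "a",
    terms_per_archetype: int = 1,
    annotation_prob: float = 0.7,
    background_prob: float = 0.05,
    seed: int = 0,
):
    """Toy ontology whose leaf terms track the planted archetypes.

    Each archetype gets a leaf term under a shared process term; archetype
    genes are annotated to their own leaf with probability
    ``annotation_prob`` and to a random other leaf with
    ``background_prob`` — so clusters recovering an archetype should show
    that leaf enriched.
    """
    import networkx as nx

    from .go_enrichment import OntologyDAG

    rng = np.random.default_rng(seed)
    table = truth.archetype_of_a if species == "a" else truth.archetype_of_b
    archs = sorted({a for a in table.values() if a not in ("constant", "never")})
    g = nx.DiGraph()
    leaves = []
    for a in archs:
        for t in range(terms_per_archetype):
            leaf = f"GO:arch{a}_{t}"
            g.add_edge(leaf, "GO:process")
            leaves.append((leaf, a))
    g.add_edge("GO:process", "GO:root")
    ann: dict[str, set[str]] = {}
    for gene, arch in table.items():
        terms = set()
        for leaf, a in leaves:
            if a == arch and rng.random() < annotation_prob:
                terms.add(leaf)
            elif rng.random() < background_prob:
                terms.add(leaf)
        if terms:
            ann[gene] = terms
    return OntologyDAG(g, ann)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(pair: SimulatedPair, outdir: str | Path) -> None:
    """Write the simulated pair in the ingest file formats plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, ds in (("a", pair.a), ("b", pair.b)):
        ingest.write_expression_table(ds.expression, out / f"species_{tag}.expr.tsv")
        ingest.write_presence_table(ds.presence, out / f"species_{tag}.presence.tsv")
        ingest.write_tf_assignments(ds.catalog, out / f"species_{tag}.tf.ass")
    ingest.write_ortholog_table(pair.orthologs, out / "orthologs.tsv")
    ingest.write_alignment(pair.alignment, out / "alignment.tsv")
    pair.truth.to_json(out / "truth.json")


def read_dataset(indir: str | Path) -> SimulatedPair:
    """Read back a dataset written by :func:`write_dataset`."""
    d = Path(indir)
    truth = SyntheticTruth.from_json(d / "truth.json")
    cfg = SimConfig(**truth.config) if truth.config else SimConfig()
    species = {"a": cfg.species_a, "b": cfg.species_b}
    sets = {}
    for tag in ("a", "b"):
        expr = ingest.read_expression_table(d / f"species_{tag}.expr.tsv", species[tag])
        pres = ingest.read_presence_table(d / f"species_{tag}.presence.tsv", species[tag])
        cat = ingest.read_tf_assignments(d / f"species_{tag}.tf.ass", species[tag])
        sets[tag] = SpeciesDataset(expr, pres, cat)
    om = ingest.read_ortholog_table(d / "orthologs.tsv", cfg.species_a, cfg.species_b)
    al = ingest.read_alignment(d / "alignment.tsv", cfg.species_a, cfg.species_b)
    return SimulatedPair(sets["a"], sets["b"], om, al, truth)
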