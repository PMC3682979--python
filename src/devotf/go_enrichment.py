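"""Ontology-term enrichment over a DAG with hierarchy decorrelation.

Annotations are propagated up the is_a/part_of DAG (true-path rule), each
term is screened with a one-sided hypergeometric test at p < 0.01, and the
*elim* procedure decorrelates the hierarchy: terms are processed from the
deepest DAG level upward, and once a term tests significant its study genes
are eliminated from every ancestor before the ancestors are tested. The
output carries both the classic and the elim p-value per term, tagged with
the algorithm name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ParseError
from .utilization import hypergeometric_overlap

log = logging.getLogger(__name__)


@dataclass
class OntologyDAG:
    """Term DAG (edges child -> parent) plus direct gene annotations."""

    graph: nx.DiGraph
    annotations: dict[str, set[str]]       # gene -> directly annotated terms
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        # make sure annotated terms exist as nodes
        for terms in self.annotations.values():
            for t in terms:
                if t not in self.graph:
                    self.graph.add_node(t)

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors_of(self, term: str) -> set[str]:
        """All terms reachable by child -> parent edges (excluding term)."""
        return set(nx.descendants(self.graph, term))

    def depths(self) -> dict[str, int]:
        """Longest-path depth from any root (term with no parents is depth 0)."""
        depth: dict[str, int] = {}
        # child -> parent edges: reverse so roots come first
        rg = self.graph.reverse(copy=False)
        for t in nx.topological_sort(rg):  # roots first
            parents = list(rg.predecessors(t))
            depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def read_ontology(
    edges_path: str | Path, annotations_path: str | Path
) -> OntologyDAG:
    """Read an edge-list TSV (``child<TAB>parent``) and a gene-term TSV."""
    g = nx.DiGraph()
    with open(edges_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError("expected child<TAB>parent", str(edges_path), lineno)
            g.add_edge(fields[0].strip(), fields[1].strip())
    ann: dict[str, set[str]] = {}
    with open(annotations_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError("expected gene<TAB>term", str(annotations_path), lineno)
            ann.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return OntologyDAG(g, ann)


def propagate_annotations(d: OntologyDAG) -> dict[str, set[str]]:
    """True-path propagation: term -> genes annotated to it or any descendant."""
    genes_at: dict[str, set[str]] = {t: set() for t in d.graph.nodes}
    for gene, terms in d.annotations.items():
        for t in terms:
            genes_at[t].add(gene)
    # child -> parent edges: process children before parents
    for t in nx.topological_sort(d.graph):
        for parent in d.graph.successors(t):
            genes_at[parent] |= genes_at[t]
    return genes_at


def classic_enrichment(
    d: OntologyDAG,
    study: set[str],
    background: set[str],
    alpha: float = 0.01,
    min_annotated: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with propagated annotations.

    Terms with fewer than ``min_annotated`` background genes, or without any
    study gene, are skipped.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    genes_at = propagate_annotations(d)
    rows = []
    for term in sorted(genes_at):
        in_bg = genes_at[term] & background
        K = len(in_bg)
        if K < min_annotated:
            continue
        k = len(in_bg & study)
        if k < 1:
            continue
        p_over, _ = hypergeometric_overlap(k, len(study), K, len(background))
        rows.append(
            {
                "term": term,
                "name": d.names.get(term, ""),
                "k": k, "n": len(study), "K": K, "N": len(background),
                "p_classic": p_over,
                "significant": p_over < alpha,
                "algorithm": "classic",
            }
        )
    return pd.DataFrame(rows)


def elim_enrichment(
    d: OntologyDAG,
    study: set[str],
    background: set[str],
    alpha: float = 0.01,
    min_annotated: int = 3,
) -> pd.DataFrame:
    """Hierarchy-decorrelated enrichment (elim procedure).

    Terms are visited from the deepest DAG level upward (ties in term-id
    order). When a term tests significant at ``alpha``, its propagated study
    genes are eliminated from the gene pools of all its ancestors before
    those are tested, so enrichment carried only by a significant descendant
    does not propagate up. Both the classic and the elim p-value are
    reported per term.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    genes_at = propagate_annotations(d)
    depths = d.depths()
    order = sorted(genes_at, key=lambda t: (-depths.get(t, 0), t))
    eliminated: dict[str, set[str]] = {t: set() for t in genes_at}
    rows = []
    for term in order:
        in_bg_classic = genes_at[term] & background
        K_classic = len(in_bg_classic)
        if K_classic < min_annotated:
            continue
        k_classic = len(in_bg_classic & study)
        if k_classic < 1:
            continue
        p_classic, _ = hypergeometric_overlap(
            k_classic, len(study), K_classic, len(background)
        )
        pool = genes_at[term] - eliminated[term]
        in_bg = pool & background
        k = len(in_bg & study)
        K = len(in_bg)
        if K == 0:
            p_elim = 1.0
        else:
            p_elim, _ = hypergeometric_overlap(k, len(study), K, len(background))
        significant = p_elim < alpha
        if significant:
            removed = genes_at[term] & study
            for anc in d.ancestors_of(term):
                if anc in eliminated:
                    eliminated[anc] |= removed
        rows.append(
            {
                "term": term,
                "name": d.names.get(term, ""),
                "k": k_classic, "n": len(study), "K": K_classic, "N": len(background),
                "p_classic": p_classic,
                "p_elim": p_elim,
                "significant": significant,
                "algorithm": "elim",
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("term").reset_index(drop=True)
    return df
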