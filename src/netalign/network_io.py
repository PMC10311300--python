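"""Input parsing and assembly of the two-species joint graph.

Reads PPI edge lists (TSV, BioGRID-style exports), typed cross-network
anchor files (ortholog pairs; sequence-similarity pairs with E-values),
and pre-propagated protein-function annotation tables, applies the
study's filtering rules (E-value cutoff, slim-term gene-count bounds,
anchor-leakage removal), and assembles a :class:`JointGraph` whose two
node-identifier namespaces are kept disjoint by species prefixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

SP1_PREFIX = "sp1:"
SP2_PREFIX = "sp2:"


class ValidationError(ValueError):
    """Input violates a structural contract (empty network, bad pair, ...)."""


class FormatError(ValueError):
    """Input file does not have the expected columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesNetwork:
    """One species' undirected PPI graph with stable string node ids."""

    species_label: str
    graph: nx.Graph

    def __post_init__(self):
        self.node_order: list[str] = sorted(self.graph.nodes)
        self.index: dict[str, int] = {u: i for i, u in enumerate(self.node_order)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges canonicalised as sorted tuples."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    def adjacency(self) -> sp.csr_matrix:
        return nx.to_scipy_sparse_array(
            self.graph, nodelist=self.node_order, dtype=np.float64,
            format="csr")

    def degrees(self) -> np.ndarray:
        return np.asarray([self.graph.degree[u] for u in self.node_order],
                          dtype=np.float64)


@dataclass
class AnchorSet:
    """Typed cross-network links (first id in G1, second in G2)."""

    edge_type: str
    pairs: set[tuple[str, str]]
    weights: dict[tuple[str, str], float] | None = None

    def __len__(self):
        return len(self.pairs)


@dataclass
class AnnotationTable:
    """Protein -> set of function-term ids (pre-propagated)."""

    mapping: dict[str, set[str]]

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.mapping.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts

    def terms(self, protein: str) -> set[str]:
        return self.mapping.get(protein, set())

    def annotated_proteins(self) -> list[str]:
        return sorted(p for p, ts in self.mapping.items() if ts)

    def restrict(self, proteins) -> "AnnotationTable":
        keep = set(proteins)
        return AnnotationTable(
            {p: set(ts) for p, ts in self.mapping.items() if p in keep})


class JointGraph:
    """Two species networks joined by typed anchor-edge sets.

    Node order is all G1 nodes (prefixed ``sp1:``) followed by all G2
    nodes (prefixed ``sp2:``); neighbour queries distinguish the
    within-network PPI context from each typed across-network context.
    """

    def __init__(self, g1: SpeciesNetwork, g2: SpeciesNetwork,
                 anchors: list[AnchorSet]):
        self.g1 = g1
        self.g2 = g2
        self.anchors = list(anchors)
        self.node_order = ([SP1_PREFIX + u for u in g1.node_order]
                           + [SP2_PREFIX + u for u in g2.node_order])
        if len(set(self.node_order)) != len(self.node_order):
            raise ValidationError("node namespaces collide even after prefixing")
        self.index = {u: i for i, u in enumerate(self.node_order)}
        self.n1 = g1.n_nodes
        self.n2 = g2.n_nodes
        self.n = self.n1 + self.n2
        self.anchor_types = [a.edge_type for a in self.anchors]
        if len(set(self.anchor_types)) != len(self.anchor_types):
            raise ValidationError("duplicate anchor edge types")
        self._by_type = {a.edge_type: a for a in self.anchors}

    # --- index helpers -------------------------------------------------
    def idx1(self, u: str) -> int:
        return self.g1.index[u]

    def idx2(self, v: str) -> int:
        return self.n1 + self.g2.index[v]

    # --- adjacency matrices -------------------------------------------
    def within_adjacency(self) -> sp.csr_matrix:
        return sp.block_diag(
            (self.g1.adjacency(), self.g2.adjacency()), format="csr")

    def anchor_adjacency(self, edge_type: str) -> sp.csr_matrix:
        if edge_type not in self._by_type:
            raise ValidationError(f"unknown anchor type {edge_type!r}")
        aset = self._by_type[edge_type]
        rows, cols = [], []
        for u, v in aset.pairs:
            i, j = self.idx1(u), self.idx2(v)
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows), dtype=np.float64)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    # --- neighbour queries ---------------------------------------------
    def n_in(self, node: str) -> set[str]:
        """Same-species PPI neighbours of a prefixed node id."""
        if node.startswith(SP1_PREFIX):
            raw = node[len(SP1_PREFIX):]
            return {SP1_PREFIX + w for w in self.g1.graph.neighbors(raw)}
        if node.startswith(SP2_PREFIX):
            raw = node[len(SP2_PREFIX):]
            return {SP2_PREFIX + w for w in self.g2.graph.neighbors(raw)}
        raise ValidationError(f"unprefixed node id {node!r}")

    def n_ac_typed(self, node: str, edge_type: str) -> set[str]:
        """Type-``edge_type`` anchor neighbours in the other species."""
        aset = self._by_type.get(edge_type)
        if aset is None:
            raise ValidationError(f"unknown anchor type {edge_type!r}")
        out: set[str] = set()
        if node.startswith(SP1_PREFIX):
            raw = node[len(SP1_PREFIX):]
            out = {SP2_PREFIX + v for u, v in aset.pairs if u == raw}
        elif node.startswith(SP2_PREFIX):
            raw = node[len(SP2_PREFIX):]
            out = {SP1_PREFIX + u for u, v in aset.pairs if v == raw}
        else:
            raise ValidationError(f"unprefixed node id {node!r}")
        return out

    def n_ac(self, node: str) -> set[str]:
        out: set[str] = set()
        for t in self.anchor_types:
            out |= self.n_ac_typed(node, t)
        return out


# ---------------------------------------------------------------------------
# loading operations
# ---------------------------------------------------------------------------

def _read_table(path, min_cols: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file has no data rows") from None
    except OSError as e:
        raise IOError(f"{path}: {e}") from e
    if df.shape[1] == 1:  # space-delimited fallback
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    if df.shape[1] < min_cols:
        raise FormatError(f"{path}: expected >= {min_cols} columns, "
                          f"got {df.shape[1]}")
    if df.shape[1] > min_cols:
        logger.info("%s: ignoring %d extra column(s)", path,
                    df.shape[1] - min_cols)
    return df


def load_network(path, species_label: str) -> SpeciesNetwork:
    """Read a two-column edge list into a SpeciesNetwork.

    Self-loops and duplicate edges are dropped (counts logged); a file
    with zero surviving edges is a validation error.
    """
    df = _read_table(path, 2)
    g = nx.Graph()
    n_self = 0
    n_dup = 0
    for u, v in zip(df[0], df[1]):
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loop(s), %d duplicate edge(s)",
                    path, n_self, n_dup)
    if g.number_of_edges() == 0:
        raise ValidationError(f"{path}: no edges after filtering")
    return SpeciesNetwork(species_label, g)


def write_network(net: SpeciesNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# edge list for {net.species_label}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def load_anchors(path, edge_type: str, g1: SpeciesNetwork,
                 g2: SpeciesNetwork,
                 evalue_cutoff: float | None = None) -> AnchorSet:
    """Read typed anchor pairs, dropping unknown nodes and (for
    similarity anchors) pairs whose E-value exceeds the cutoff."""
    df = _read_table(path, 2)
    if evalue_cutoff is not None and df.shape[1] < 3:
        raise FormatError(f"{path}: E-value cutoff given but no third column")
    pairs: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    n_unknown = 0
    n_cut = 0
    for row in df.itertuples(index=False):
        u, v = row[0], row[1]
        if u not in g1.index or v not in g2.index:
            n_unknown += 1
            continue
        if evalue_cutoff is not None:
            ev = float(row[2])
            if ev > evalue_cutoff:
                n_cut += 1
                continue
            weights[(u, v)] = ev
        pairs.add((u, v))
    if n_unknown or n_cut:
        logger.info("%s: dropped %d pair(s) with unknown nodes, "
                    "%d above E-value cutoff", path, n_unknown, n_cut)
    return AnchorSet(edge_type, pairs, weights or None)


def write_anchors(aset: AnchorSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# anchors type={aset.edge_type}\n")
        for u, v in sorted(aset.pairs):
            if aset.weights is not None:
                fh.write(f"{u}\t{v}\t{aset.weights.get((u, v), 0.0):.3e}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def load_annotations(path) -> AnnotationTable:
    """Read a two-column (protein, term) table into an AnnotationTable."""
    df = _read_table(path, 2)
    mapping: dict[str, set[str]] = {}
    for p, t in zip(df[0], df[1]):
        mapping.setdefault(p, set()).add(t)
    return AnnotationTable(mapping)


def write_annotations(ann: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tterm\n")
        for p in sorted(ann.mapping):
            for t in sorted(ann.mapping[p]):
                fh.write(f"{p}\t{t}\n")


# ---------------------------------------------------------------------------
# filtering operations
# ---------------------------------------------------------------------------

def pooled_term_counts(*tables: AnnotationTable) -> dict[str, int]:
    """Per-term annotated-gene counts over the union of the tables."""
    counts: dict[str, int] = {}
    for tab in tables:
        for t, c in tab.term_counts().items():
            counts[t] = counts.get(t, 0) + c
    return counts


def slim_filter(ann: AnnotationTable, min_genes: int, max_genes: int,
                extra_terms: set[str] = frozenset(),
                term_counts: dict[str, int] | None = None) -> AnnotationTable:
    """Keep only terms annotating between ``min_genes`` and ``max_genes``
    genes (inclusive), or listed in ``extra_terms`` (curated slim terms).

    ``term_counts`` lets the caller supply counts pooled over both
    species' tables; by default counts come from ``ann`` itself.
    Proteins left with no surviving terms are retained with empty sets.
    """
    if min_genes > max_genes:
        raise ValidationError("min_genes > max_genes")
    counts = term_counts if term_counts is not None else ann.term_counts()
    keep = {t for t, c in counts.items()
            if min_genes <= c <= max_genes} | set(extra_terms)
    return AnnotationTable(
        {p: {t for t in ts if t in keep} for p, ts in ann.mapping.items()})


def remove_leaky_anchors(anchors: AnchorSet, ann1: AnnotationTable,
                         ann2: AnnotationTable) -> AnchorSet:
    """Drop anchor pairs whose two proteins share any function term.

    Such anchors coincide with positive labels and would leak the
    supervision signal into the graph structure.
    """
    kept: set[tuple[str, str]] = set()
    for u, v in anchors.pairs:
        if ann1.terms(u) & ann2.terms(v):
            continue
        kept.add((u, v))
    n_dropped = len(anchors.pairs) - len(kept)
    if n_dropped:
        logger.info("anchor type %s: removed %d leaky pair(s)",
                    anchors.edge_type, n_dropped)
    weights = None
    if anchors.weights is not None:
        weights = {p: w for p, w in anchors.weights.items() if p in kept}
    return AnchorSet(anchors.edge_type, kept, weights)


def build_joint_graph(g1: SpeciesNetwork, g2: SpeciesNetwork,
                      anchors: list[AnchorSet]) -> JointGraph:
    """Assemble the integrated graph, validating anchor endpoints."""
    cleaned = []
    for aset in anchors:
        kept = {(u, v) for u, v in aset.pairs
                if u in g1.index and v in g2.index}
        n_dropped = len(aset.pairs) - len(kept)
        if n_dropped:
            logger.info("anchor type %s: dropped %d pair(s) with endpoints "
                        "outside the networks", aset.edge_type, n_dropped)
        weights = None
        if aset.weights is not None:
            weights = {p: w for p, w in aset.weights.items() if p in kept}
        cleaned.append(AnchorSet(aset.edge_type, kept, weights))
    return JointGraph(g1, g2, cleaned)
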