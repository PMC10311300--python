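"""Synthetic two-species benchmark instances with a planted node
correspondence.

A source PPI-like network G1 is sampled (duplication–divergence by
default, matching the heavy-tailed degree distributions of real PPIs);
G2 is a node-relabelled copy perturbed by edge deletions and spurious
insertions.  Anchor links are a noisy subset of the true correspondence,
split into a high-precision "ortholog" set and a lower-precision
"seqsim" set carrying synthetic E-values.  Function terms are planted as
topological modules (BFS balls around seed nodes) in G1 and copied to
the mapped G2 nodes with a flip rate — mirroring how real annotations
are enriched in network neighbourhoods — which yields many-to-many
functional-relatedness labels that are predictable from topology plus
anchors, the structure the aligner is meant to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import sampling
from .network_io import (AnchorSet, AnnotationTable, JointGraph,
                         SpeciesNetwork, ValidationError, build_joint_graph,
                         write_anchors, write_annotations, write_network)


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the benchmark conditions."""

    n_nodes: int = 300
    edge_model: str = "duplication_divergence"  # | erdos_renyi | barabasi_albert
    edge_params: dict = field(default_factory=dict)
    p_delete: float = 0.1        # per-edge deletion prob deriving G2
    p_insert: float = 0.1        # spurious edges added as fraction of |E1|
    anchor_recall: float = 0.5   # fraction of true correspondences emitted
    anchor_noise: float = 0.05   # spurious anchors as fraction of true ones
    ortholog_share: float = 0.6  # fraction of true anchors typed "ortholog"
    n_terms: int = 40
    term_module_size: tuple = (4, 15)  # nodes per planted function module
    term_flip: float = 0.1       # per-annotation loss rate when copying to G2
    seed: int = 20240101

    def __post_init__(self):
        for p in (self.p_delete, self.p_insert, self.anchor_recall,
                  self.anchor_noise, self.term_flip):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.n_nodes < 10:
            raise ValidationError("n_nodes must be >= 10")


@dataclass
class SyntheticInstance:
    jg: JointGraph
    true_mapping: dict[str, str]   # g1 node -> g2 node
    ann1: AnnotationTable
    ann2: AnnotationTable
    ground_truth_pairs: set[tuple[str, str]]
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# network models
# ---------------------------------------------------------------------------

def _duplication_divergence(n: int, rng: np.random.Generator,
                            retain: float = 0.4,
                            p_parent: float = 0.15) -> nx.Graph:
    """Grow a graph by node duplication: a duplicate keeps each of its
    parent's edges with prob ``retain`` and links to the parent with
    prob ``p_parent``; orphaned duplicates attach to the parent."""
    g = nx.complete_graph(3)
    while g.number_of_nodes() < n:
        v = g.number_of_nodes()
        u = int(rng.integers(v))
        g.add_node(v)
        for w in list(g.neighbors(u)):
            if rng.random() < retain:
                g.add_edge(v, w)
        if rng.random() < p_parent:
            g.add_edge(v, u)
        if g.degree[v] == 0:
            g.add_edge(v, u)
    return g


def _sample_g1(spec: SyntheticSpec, rng: np.random.Generator) -> nx.Graph:
    n = spec.n_nodes
    if spec.edge_model == "duplication_divergence":
        return _duplication_divergence(n, rng, **spec.edge_params)
    if spec.edge_model == "erdos_renyi":
        p = spec.edge_params.get("p", 4.0 / n)
        return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if spec.edge_model == "barabasi_albert":
        m = spec.edge_params.get("m", 2)
        return nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    raise ValidationError(f"unknown edge model {spec.edge_model!r}")


def _perturb_copy(g1: nx.Graph, mapping: dict, spec: SyntheticSpec,
                  rng: np.random.Generator) -> nx.Graph:
    """Relabel G1 through the planted correspondence, delete edges with
    prob p_delete, insert p_insert*|E1| spurious non-edges, then re-add
    one deleted edge for any node left isolated (so the correspondence
    stays total over PPI-present nodes)."""
    g2 = nx.Graph()
    g2.add_nodes_from(mapping.values())
    deleted: list[tuple] = []
    for u, v in g1.edges:
        e = (mapping[u], mapping[v])
        if rng.random() < spec.p_delete:
            deleted.append(e)
        else:
            g2.add_edge(*e)
    nodes2 = sorted(g2.nodes)
    n_insert = int(round(spec.p_insert * g1.number_of_edges()))
    inserted = 0
    while inserted < n_insert:
        a, b = rng.choice(len(nodes2), size=2, replace=False)
        u, v = nodes2[a], nodes2[b]
        if not g2.has_edge(u, v):
            g2.add_edge(u, v)
            inserted += 1
    for u, v in deleted:
        if g2.degree[u] == 0 or g2.degree[v] == 0:
            g2.add_edge(u, v)
    return g2


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> SyntheticInstance:
    """Sample a full instance; fully reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    raw1 = _sample_g1(spec, rng)
    raw1.remove_nodes_from(list(nx.isolates(raw1)))
    name1 = {u: f"x{idx:04d}" for idx, u in enumerate(sorted(raw1.nodes))}
    g1_graph = nx.relabel_nodes(raw1, name1)
    n = g1_graph.number_of_nodes()
    perm = rng.permutation(n)
    g1_nodes = sorted(g1_graph.nodes)
    mapping = {u: f"y{perm[i]:04d}" for i, u in enumerate(g1_nodes)}
    g2_graph = _perturb_copy(g1_graph, mapping, spec, rng)
    g1 = SpeciesNetwork("species1", g1_graph)
    g2 = SpeciesNetwork("species2", g2_graph)

    # --- anchors ------------------------------------------------------
    true_pairs = sorted(mapping.items())
    n_true = int(round(spec.anchor_recall * len(true_pairs)))
    chosen = rng.choice(len(true_pairs), size=n_true, replace=False)
    emitted = [true_pairs[i] for i in sorted(chosen)]
    n_noise = int(round(spec.anchor_noise * n_true))
    noise: set[tuple[str, str]] = set()
    g2_nodes = sorted(g2_graph.nodes)
    truth_set = set(true_pairs)
    while len(noise) < n_noise:
        p = g1_nodes[rng.integers(n)]
        q = g2_nodes[rng.integers(n)]
        if (p, q) not in truth_set:
            noise.add((p, q))
    n_orth = int(round(spec.ortholog_share * len(emitted)))
    orth_pairs = set(emitted[:n_orth])
    seq_pairs = set(emitted[n_orth:])
    noise = sorted(noise)
    n_orth_noise = int(round(0.2 * len(noise)))  # seqsim is lower precision
    orth_pairs |= set(noise[:n_orth_noise])
    seq_pairs |= set(noise[n_orth_noise:])
    seq_ev = {pair: 10.0 ** -float(rng.uniform(7.0, 30.0))
              for pair in seq_pairs}
    anchors = [AnchorSet("ortholog", orth_pairs),
               AnchorSet("seqsim", seq_pairs, seq_ev)]

    # --- planted function modules -------------------------------------
    lo, hi = spec.term_module_size
    ann1_map: dict[str, set[str]] = {u: set() for u in g1_nodes}
    ann2_map: dict[str, set[str]] = {v: set() for v in g2_nodes}
    for t_idx in range(spec.n_terms):
        term = f"T{t_idx:04d}"
        size = int(rng.integers(lo, hi + 1))
        seedn = g1_nodes[rng.integers(n)]
        members: list[str] = []
        for node in nx.bfs_tree(g1_graph, seedn):
            members.append(node)
            if len(members) >= size:
                break
        for u in members:
            ann1_map[u].add(term)
            if rng.random() >= spec.term_flip:
                ann2_map[mapping[u]].add(term)
            else:  # annotation lost in copy; re-plant on a random node
                ann2_map[g2_nodes[rng.integers(n)]].add(term)
    ann1 = AnnotationTable(ann1_map)
    ann2 = AnnotationTable(ann2_map)

    jg = build_joint_graph(g1, g2, anchors)
    ground_truth = sampling.build_positives(ann1, ann2, jg)
    if not ground_truth:
        raise ValidationError("generated instance has an empty positive set")
    return SyntheticInstance(jg, mapping, ann1, ann2, ground_truth, spec)


def default_instance() -> SyntheticInstance:
    """The fixed benchmark instance used throughout the test suite:
    n=300 duplication–divergence source, 10% edge deletion/insertion,
    anchor recall 0.5 with 5% spurious anchors, 40 planted terms."""
    return generate(SyntheticSpec())


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_instance(inst: SyntheticInstance, outdir) -> None:
    """Write the standard file set consumable by prepare/train."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(inst.jg.g1, outdir / "g1.edges.tsv")
    write_network(inst.jg.g2, outdir / "g2.edges.tsv")
    for aset in inst.jg.anchors:
        write_anchors(aset, outdir / f"anchors.{aset.edge_type}.tsv")
    merged = AnnotationTable({**inst.ann1.mapping, **inst.ann2.mapping})
    write_annotations(merged, outdir / "annotations.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("# g1_node\tg2_node\n")
        for u, v in sorted(inst.true_mapping.items()):
            fh.write(f"{u}\t{v}\n")
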