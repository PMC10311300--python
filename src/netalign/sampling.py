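"""Labelled pair construction: shared-function positives, easy /
semi-hard / hard negative sampling, and node-disjoint train/valid/test
splits.

Supervised alignment is positive-unlabeled: only related pairs are
observed.  Negatives are sampled from one of three candidate universes,

    easy      = V1 x V2 \\ positives
    semi_hard = (V1p x V2) u (V1 x V2p) \\ positives
    hard      = V1p x V2p \\ positives

where Vkp are the proteins involved in positive pairs.  Hard negatives
force the classifier to learn pair relatedness rather than whether a
node appears in the training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_io import AnnotationTable, JointGraph, ValidationError

logger = logging.getLogger(__name__)

MODES = ("easy", "semi_hard", "hard")

#: candidate universes up to this size are enumerated explicitly
ENUMERATION_LIMIT = 10_000_000


@dataclass
class PairSet:
    """Labelled cross-species pairs (raw, unprefixed node ids)."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    sampling_mode: str
    seed: int

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValidationError("positives and negatives overlap")

    def as_arrays(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        pairs = sorted(self.positives) + sorted(self.negatives)
        labels = np.r_[np.ones(len(self.positives)),
                       np.zeros(len(self.negatives))]
        return pairs, labels

    def to_tsv(self, path, split: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("# node1\tnode2\tlabel\tsplit\n")
            for u, v in sorted(self.positives):
                fh.write(f"{u}\t{v}\t1\t{split}\n")
            for u, v in sorted(self.negatives):
                fh.write(f"{u}\t{v}\t0\t{split}\n")

    @classmethod
    def from_tsv(cls, path, sampling_mode: str = "easy",
                 seed: int = 0) -> "PairSet":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        pos = {(r[0], r[1]) for r in df.itertuples(index=False)
               if int(r[2]) == 1}
        neg = {(r[0], r[1]) for r in df.itertuples(index=False)
               if int(r[2]) == 0}
        return cls(pos, neg, sampling_mode, seed)


@dataclass
class SplitSpec:
    """Per-species node partition; test nodes never occur in train/valid."""

    nodes1: dict[str, list[str]]  # split name -> g1 node ids
    nodes2: dict[str, list[str]]
    ratio: float
    seed: int
    n_straddling: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"nodes1": self.nodes1, "nodes2": self.nodes2,
                       "ratio": self.ratio, "seed": self.seed,
                       "n_straddling": self.n_straddling}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SplitSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["nodes1"], d["nodes2"], d["ratio"], d["seed"],
                   d["n_straddling"])


# ---------------------------------------------------------------------------
# positives
# ---------------------------------------------------------------------------

def build_positives(ann1: AnnotationTable, ann2: AnnotationTable,
                    jg: JointGraph) -> set[tuple[str, str]]:
    """All cross-species pairs sharing at least one (slim-filtered)
    function term, restricted to PPI-present proteins."""
    by_term1: dict[str, list[str]] = {}
    for p, terms in ann1.mapping.items():
        if p not in jg.g1.index:
            continue
        for t in terms:
            by_term1.setdefault(t, []).append(p)
    positives: set[tuple[str, str]] = set()
    for q, terms in ann2.mapping.items():
        if q not in jg.g2.index:
            continue
        for t in terms:
            for p in by_term1.get(t, ()):
                positives.add((p, q))
    return positives


def positive_nodes(positives) -> tuple[set[str], set[str]]:
    """(V1p, V2p): per-species proteins involved in positive pairs."""
    return {p for p, _ in positives}, {q for _, q in positives}


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def candidate_negatives(positives: set[tuple[str, str]], mode: str,
                        nodes1, nodes2) -> set[tuple[str, str]]:
    """Explicit candidate universe for a mode (small instances only)."""
    if mode not in MODES:
        raise ValidationError(f"unknown sampling mode {mode!r}")
    nodes1, nodes2 = sorted(nodes1), sorted(nodes2)
    v1p, v2p = positive_nodes(positives)
    if mode == "easy":
        cands = {(p, q) for p in nodes1 for q in nodes2}
    elif mode == "semi_hard":
        cands = {(p, q) for p in nodes1 for q in nodes2
                 if p in v1p or q in v2p}
    else:
        cands = {(p, q) for p in nodes1 if p in v1p
                 for q in nodes2 if q in v2p}
    return cands - positives


def sample_negatives(positives: set[tuple[str, str]], jg: JointGraph,
                     mode: str, n_samples: int, seed: int,
                     nodes1=None, nodes2=None) -> set[tuple[str, str]]:
    """Uniform sample without replacement from the mode's candidate set.

    ``nodes1``/``nodes2`` restrict the universe (e.g. to one split's
    nodes); default is all PPI nodes.  Large universes are rejection-
    sampled instead of enumerated.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown sampling mode {mode!r}")
    nodes1 = sorted(nodes1 if nodes1 is not None else jg.g1.node_order)
    nodes2 = sorted(nodes2 if nodes2 is not None else jg.g2.node_order)
    v1p, v2p = positive_nodes(positives)
    if mode == "hard":
        pool1 = sorted(set(nodes1) & v1p)
        pool2 = sorted(set(nodes2) & v2p)
    else:
        pool1, pool2 = nodes1, nodes2
    rng = np.random.default_rng(seed)
    universe = len(pool1) * len(pool2)
    if universe <= ENUMERATION_LIMIT:
        cands = sorted(candidate_negatives(positives, mode, nodes1, nodes2))
        if n_samples > len(cands):
            raise ValidationError(
                f"requested {n_samples} negatives but only {len(cands)} "
                f"candidates exist in mode {mode!r}")
        idx = rng.choice(len(cands), size=n_samples, replace=False)
        return {cands[i] for i in idx}
    # rejection sampling for genome-scale universes
    out: set[tuple[str, str]] = set()
    attempts = 0
    max_attempts = 200 * n_samples
    while len(out) < n_samples and attempts < max_attempts:
        attempts += 1
        p = pool1[rng.integers(len(pool1))]
        q = pool2[rng.integers(len(pool2))]
        if mode == "semi_hard" and p not in v1p and q not in v2p:
            continue
        if (p, q) in positives or (p, q) in out:
            continue
        out.add((p, q))
    if len(out) < n_samples:
        raise ValidationError(
            f"rejection sampling produced only {len(out)} of "
            f"{n_samples} negatives")
    return out


# ---------------------------------------------------------------------------
# node-disjoint splits
# ---------------------------------------------------------------------------

def _split_units(units: list[list[str]], ratio: float,
                 valid_fraction: float,
                 rng: np.random.Generator) -> tuple[list, list, list]:
    """Partition indivisible node units into train/valid/test by
    cumulative node count."""
    perm = rng.permutation(len(units))
    total = sum(len(u) for u in units)
    n_test = int(round((1 - ratio) * total))
    test: list[str] = []
    rest: list[list[str]] = []
    for i in perm:
        if len(test) < n_test:
            test += units[i]
        else:
            rest.append(units[i])
    n_valid = int(round(valid_fraction * sum(len(u) for u in rest)))
    valid: list[str] = []
    train: list[str] = []
    for u in rest:
        if len(valid) < n_valid:
            valid += u
        else:
            train += u
    return train, valid, test


def negative_resampler(jg: JointGraph, positives: set[tuple[str, str]],
                       spec: "SplitSpec", mode: str, n_samples: int):
    """Factory for per-epoch training-negative resampling: returns a
    callable mapping an epoch seed to a fresh negative set drawn from
    the train split's candidate universe."""

    def resample(epoch_seed: int) -> set[tuple[str, str]]:
        return sample_negatives(positives, jg, mode, n_samples,
                                seed=epoch_seed,
                                nodes1=spec.nodes1["train"],
                                nodes2=spec.nodes2["train"])

    return resample


def _cluster_units(nodes: list[str],
                   clusters: dict[str, str] | None) -> list[list[str]]:
    """Group nodes into indivisible units (cluster members stay
    together; unclustered nodes are singletons)."""
    if not clusters:
        return [[u] for u in sorted(nodes)]
    by_cluster: dict[str, list[str]] = {}
    singletons: list[list[str]] = []
    for u in sorted(nodes):
        c = clusters.get(u)
        if c is None:
            singletons.append([u])
        else:
            by_cluster.setdefault(c, []).append(u)
    return sorted(by_cluster.values()) + singletons


def make_split(jg: JointGraph, positives: set[tuple[str, str]],
               ratio: float = 0.8, seed: int = 0,
               valid_fraction: float = 0.1, mode: str = "hard",
               neg_ratio: float = 1.0,
               valid_includes_straddling: bool = True,
               clusters1: dict[str, str] | None = None,
               clusters2: dict[str, str] | None = None
               ) -> tuple[SplitSpec, dict[str, PairSet]]:
    """Node-disjoint 8:2 split with validation carved from train.

    Nodes (per species) are partitioned, stratified so positive-involved
    nodes respect the ratio.  A train pair needs both endpoints in the
    train nodes and a test pair both endpoints in the test nodes; pairs
    touching a test node and a non-test node are discarded (counted).
    With ``valid_includes_straddling`` (default) a pair with a valid
    endpoint and a train-or-valid endpoint counts as validation — valid
    nodes never occur in training pairs, so model selection stays
    honest, and the validation set is large enough to be stable; with
    the flag off only both-valid pairs are kept.  Negatives are sampled
    per split from that split's node universe only.
    """
    rng = np.random.default_rng(seed)
    v1p, v2p = positive_nodes(positives)
    splits1: dict[str, list[str]] = {"train": [], "valid": [], "test": []}
    splits2: dict[str, list[str]] = {"train": [], "valid": [], "test": []}
    for nodes, vp, clusters, out in (
            (jg.g1.node_order, v1p, clusters1, splits1),
            (jg.g2.node_order, v2p, clusters2, splits2)):
        if clusters:
            # cluster-disjoint split: members stay together, which
            # precludes stratifying on positive involvement
            strata = [_cluster_units(nodes, clusters)]
        else:
            strata = [_cluster_units(sorted(set(nodes) & vp), None),
                      _cluster_units(sorted(set(nodes) - vp), None)]
        for units in strata:
            tr, va, te = _split_units(units, ratio, valid_fraction, rng)
            out["train"] += tr
            out["valid"] += va
            out["test"] += te
    member1 = {u: s for s, us in splits1.items() for u in us}
    member2 = {v: s for s, vs in splits2.items() for v in vs}
    pos_by_split: dict[str, set] = {s: set() for s in splits1}
    n_straddling = 0
    for p, q in positives:
        s1, s2 = member1[p], member2[q]
        if s1 == s2:
            pos_by_split[s1].add((p, q))
        elif valid_includes_straddling and "test" not in (s1, s2):
            pos_by_split["valid"].add((p, q))
        else:
            n_straddling += 1
    logger.info("split: %s positives per split, %d straddling discarded",
                {s: len(v) for s, v in pos_by_split.items()}, n_straddling)
    pairsets: dict[str, PairSet] = {}
    for i, s in enumerate(("train", "valid", "test")):
        pos = pos_by_split[s]
        if not pos:
            raise ValidationError(f"split {s!r} has zero positives")
        n_neg = int(round(neg_ratio * len(pos)))
        if s == "valid" and valid_includes_straddling:
            tv1 = splits1["train"] + splits1["valid"]
            tv2 = splits2["train"] + splits2["valid"]
            cands = (candidate_negatives(positives, mode,
                                         splits1["valid"], tv2)
                     | candidate_negatives(positives, mode,
                                           tv1, splits2["valid"]))
            cands -= pairsets["train"].negatives
            cands = sorted(cands)
            if n_neg > len(cands):
                raise ValidationError(
                    f"requested {n_neg} valid negatives but only "
                    f"{len(cands)} candidates exist")
            pick = np.random.default_rng(seed + 1000 + i).choice(
                len(cands), size=n_neg, replace=False)
            neg = {cands[k] for k in pick}
        else:
            neg = sample_negatives(positives, jg, mode, n_neg,
                                   seed=seed + 1000 + i,
                                   nodes1=splits1[s], nodes2=splits2[s])
        pairsets[s] = PairSet(pos, neg, mode, seed)
    spec = SplitSpec(splits1, splits2, ratio, seed, n_straddling)
    return spec, pairsets
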