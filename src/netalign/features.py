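"""Initial node features: NetMF distance embeddings and Laplacian
positional embeddings, computed per species network.

The NetMF matrix is the closed-form random-walk co-occurrence matrix

    M = vol(G) / (b * T) * (sum_{r=1..T} (D^-1 A)^r) * D^-1

whose entry M_ij approximates the number of length-<=T walk co-visits
between i and j; its row-wise truncated logarithm log(max(M, 1)) is the
distance feature of node i.  Positional features are the eigenvectors of
the symmetric-normalised Laplacian L = I - D^{-1/2} A D^{-1/2} for the
d smallest non-trivial eigenvalues (one near-zero eigenvalue per
connected component is skipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .network_io import SpeciesNetwork, ValidationError

#: graphs at or below this size use dense linear algebra throughout
DENSE_LIMIT = 2000

#: eigenvalues below this are treated as the trivial (component) modes
TRIVIAL_EIG_TOL = 1e-8


@dataclass
class EmbeddingMatrix:
    """Per-node feature rows; row order matches ``node_order`` exactly."""

    node_order: list[str]
    values: np.ndarray
    kind: str  # "distance_raw" | "positional"

    def __post_init__(self):
        if self.values.shape[0] != len(self.node_order):
            raise ValidationError("row count does not match node order")

    @property
    def dims(self) -> tuple[int, int]:
        return self.values.shape

    def save(self, prefix: str) -> None:
        """Write as a text pair: ``<prefix>.nodes`` and ``<prefix>.tsv``."""
        with open(f"{prefix}.nodes", "w") as fh:
            fh.write(self.kind + "\n")
            for u in self.node_order:
                fh.write(u + "\n")
        np.savetxt(f"{prefix}.tsv", self.values, delimiter="\t")

    @classmethod
    def load(cls, prefix: str) -> "EmbeddingMatrix":
        with open(f"{prefix}.nodes") as fh:
            lines = fh.read().splitlines()
        kind, node_order = lines[0], lines[1:]
        values = np.atleast_2d(np.loadtxt(f"{prefix}.tsv", delimiter="\t"))
        return cls(node_order, values, kind)


# ---------------------------------------------------------------------------
# NetMF distance embeddings
# ---------------------------------------------------------------------------

def netmf_matrix(g: SpeciesNetwork, window_T: int = 10,
                 neg_b: float = 1.0) -> np.ndarray:
    """Closed-form NetMF co-occurrence matrix (dense n x n, symmetric).

    Uses dense powers for graphs up to ``DENSE_LIMIT`` nodes and sparse
    iterated products above.  Zero-degree nodes are excluded at load
    time, so every degree is >= 1 here.
    """
    if g.n_edges == 0:
        raise ValidationError("netmf_matrix needs at least one edge")
    if window_T < 1:
        raise ValidationError("window_T must be >= 1")
    deg = g.degrees()
    if np.any(deg == 0):
        raise ValidationError("zero-degree node present; drop isolated "
                              "nodes before computing features")
    vol = float(deg.sum())
    n = g.n_nodes
    if n <= DENSE_LIMIT:
        A = g.adjacency().toarray()
        P = A / deg[:, None]  # D^-1 A
        acc = np.zeros_like(P)
        Pr = np.eye(n)
        for _ in range(window_T):
            Pr = Pr @ P
            acc += Pr
    else:
        A = g.adjacency()
        P = sp.diags(1.0 / deg) @ A  # sparse row-stochastic
        acc = np.zeros((n, n))
        Pr = np.eye(n)
        for _ in range(window_T):
            Pr = P @ Pr
            acc += Pr
    M = (vol / (neg_b * window_T)) * (acc / deg[None, :])
    return M


def distance_embedding(M: np.ndarray) -> np.ndarray:
    """Truncated logarithm of the NetMF matrix: log(max(M, 1)).

    Entries below 1 (rare co-visits) map to 0, following the truncated-
    logarithm convention of the NetMF factorisation.
    """
    return np.log(np.maximum(M, 1.0))


def distance_features(g: SpeciesNetwork, window_T: int = 10,
                      neg_b: float = 1.0) -> EmbeddingMatrix:
    M = netmf_matrix(g, window_T=window_T, neg_b=neg_b)
    return EmbeddingMatrix(list(g.node_order), distance_embedding(M),
                           "distance_raw")


# ---------------------------------------------------------------------------
# Laplacian positional embeddings
# ---------------------------------------------------------------------------

def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties: first
    index), so eigenvectors are deterministic across runs/platforms."""
    U = U.copy()
    for c in range(U.shape[1]):
        col = U[:, c]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            U[:, c] = -col
    return U


def laplacian_positional(g: SpeciesNetwork, d: int) -> EmbeddingMatrix:
    """Eigenvectors of the symmetric-normalised Laplacian for the ``d``
    smallest non-trivial eigenvalues.

    Exactly one near-zero eigenvalue per connected component is skipped
    (tolerance 1e-8).  Within a degenerate eigenspace the embedding is
    defined only up to rotation; columns are ordered by eigenvalue and
    sign-fixed for determinism.
    """
    A = g.adjacency()
    n = g.n_nodes
    n_comp = csgraph.connected_components(A, directed=False,
                                          return_labels=False)
    max_d = n - n_comp
    if d < 1 or d > max_d:
        raise ValidationError(
            f"d={d} not feasible; graph supports at most {max_d} "
            "non-trivial eigenvectors")
    deg = g.degrees()
    dinv_sqrt = 1.0 / np.sqrt(deg)
    if n <= DENSE_LIMIT:
        L = np.eye(n) - (dinv_sqrt[:, None] * A.toarray() * dinv_sqrt[None, :])
        evals, evecs = scipy.linalg.eigh(L)
    else:
        L = sp.eye(n) - sp.diags(dinv_sqrt) @ A @ sp.diags(dinv_sqrt)
        k = min(d + n_comp + 2, n - 1)
        evals, evecs = spla.eigsh(L.tocsc(), k=k, sigma=-1e-3, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    nontrivial = evals >= TRIVIAL_EIG_TOL
    n_skipped = int(np.sum(~nontrivial[:n_comp + d]))
    if n_skipped != n_comp:
        # more near-zero modes than components can only happen at
        # pathological tolerance boundaries; report rather than guess
        raise ValidationError(
            f"expected {n_comp} trivial eigenvalue(s), found {n_skipped}")
    U = evecs[:, nontrivial][:, :d]
    return EmbeddingMatrix(list(g.node_order), _fix_signs(U), "positional")
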