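"""Block transition matrix for the heterogeneous random walk.

The walker moves over three layers (diseases, proteins, drugs). Nine
small-scale blocks give the transition probabilities between and within
layers; they derive from the adjacency matrices by row normalization:

* within-layer blocks come from the similarity / interaction matrices (S5,
  S3, S4) with self-similarity diagonals zeroed so a node cannot hoard
  probability on itself;
* cross-layer blocks come from the bipartite associations (S1, S2, S6 and
  their transposes). Under the ``no_prior`` strategy the drug<->disease
  blocks are identically zero so known treatment links cannot bias the
  predictions; the ``full`` strategy keeps them.

Layer weights (a, b, c) with a + b + c = 1 split each source node's outgoing
mass between the disease, protein and drug layers; layers the node cannot
reach are dropped and the weights renormalized over the reachable ones, so
every non-dangling row of the assembled matrix sums to one. A final min-max
rescaling by the global maximum entry (minimum taken as the structural zero)
speeds up convergence of the iteration without reordering any transition
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import HeteroNetwork

__all__ = [
    "LayerWeights",
    "TransitionMatrix",
    "build_blocks",
    "weight_and_assemble",
    "minmax_normalize",
    "build_transition",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("no_prior", "full")
LAYERS = ("disease", "protein", "drug")


@dataclass(frozen=True)
class LayerWeights:
    """Importance weights of the disease (a), protein (b) and drug (c) layers.

    They act on both the seed profile and the transition process; the sum of
    a, b and c is 1. The refined default is a=0.5, b=0.4, c=0.1.
    """

    a: float = 0.5
    b: float = 0.4
    c: float = 0.1

    def __post_init__(self) -> None:
        for name, v in zip("abc", (self.a, self.b, self.c)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"layer weight {name}={v} outside [0, 1]")
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError(
                f"the sum of a, b, and c must be 1 (got {self.a + self.b + self.c})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass
class TransitionMatrix:
    """The assembled square transition matrix with its provenance.

    ``matrix`` spans (diseases, proteins, drugs) concatenated in that order.
    ``scale`` records the global maximum divided out by min-max
    normalization (1.0 if not yet normalized); ``dangling`` flags nodes with
    no outgoing transitions (their rows are zero — the restart term keeps the
    walk well defined).
    """

    matrix: sp.csr_matrix
    strategy: str
    weights: LayerWeights
    layer_sizes: tuple[int, int, int]
    scale: float = 1.0
    dangling: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = sum(self.layer_sizes)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != layer sizes {self.layer_sizes}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("transition matrix has negative entries")

    def block(self, src: str, dst: str) -> sp.csr_matrix:
        """Extract the transition block from layer ``src`` to layer ``dst``."""
        offs = np.concatenate([[0], np.cumsum(self.layer_sizes)])
        i, j = LAYERS.index(src), LAYERS.index(dst)
        return sp.csr_matrix(
            self.matrix[offs[i]:offs[i + 1], offs[j]:offs[j + 1]]
        )


def _row_normalize(m: sp.spmatrix) -> sp.csr_matrix:
    """Scale every nonzero row to sum 1; zero rows stay zero."""
    m = sp.csr_matrix(m, dtype=float)
    sums = np.asarray(m.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.csr_matrix(sp.diags(inv) @ m)


def _zero_diagonal(m) -> sp.csr_matrix:
    m = sp.csr_matrix(m, dtype=float)
    m = sp.lil_matrix(m)
    m.setdiag(0.0)
    return sp.csr_matrix(m)


def build_blocks(net: HeteroNetwork, strategy: str) -> dict[tuple[str, str], sp.csr_matrix]:
    """Row-normalized raw transition blocks keyed by (source, destination) layer.

    Each block is the corresponding adjacency (or its transpose) with rows
    scaled to sum one. Self-similarity diagonals of the drug and disease
    similarity matrices are removed first. Under ``no_prior`` the
    disease<->drug blocks are zero regardless of S6.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    nd, np_, ng = len(net.diseases), len(net.proteins), len(net.drugs)
    s1 = sp.csr_matrix(net.S1, dtype=float)
    s2 = sp.csr_matrix(net.S2, dtype=float)
    blocks = {
        ("disease", "disease"): _row_normalize(_zero_diagonal(net.S5)),
        ("disease", "protein"): _row_normalize(s1),
        ("protein", "disease"): _row_normalize(s1.T),
        ("protein", "protein"): _row_normalize(net.S3),
        ("protein", "drug"): _row_normalize(s2),
        ("drug", "protein"): _row_normalize(s2.T),
        ("drug", "drug"): _row_normalize(_zero_diagonal(net.S4)),
    }
    if strategy == "full":
        s6 = sp.csr_matrix(net.S6, dtype=float)
        blocks[("drug", "disease")] = _row_normalize(s6)
        blocks[("disease", "drug")] = _row_normalize(s6.T)
    else:
        blocks[("drug", "disease")] = sp.csr_matrix((ng, nd))
        blocks[("disease", "drug")] = sp.csr_matrix((nd, ng))
    return blocks


def weight_and_assemble(
    blocks: dict[tuple[str, str], sp.csr_matrix],
    weights: LayerWeights,
    strategy: str = "no_prior",
) -> TransitionMatrix:
    """Combine the nine blocks into one matrix under the layer weights.

    For each source node the outgoing mass is split between destination
    layers proportionally to (a, b, c), restricted to the layers where the
    node actually has transitions and renormalized over those. Nodes with no
    outgoing edges anywhere keep a zero row and are recorded as dangling.
    """
    layer_sizes = tuple(blocks[(l, l)].shape[0] for l in LAYERS)
    w = dict(zip(LAYERS, weights.as_tuple()))
    weighted_rows: list[sp.csr_matrix] = []
    dangling_parts: list[np.ndarray] = []
    for src in LAYERS:
        row_blocks = {dst: blocks[(src, dst)] for dst in LAYERS}
        # which destination layers each source node can reach
        reach = {
            dst: np.asarray(b.sum(axis=1)).ravel() > 0 for dst, b in row_blocks.items()
        }
        denom = sum(w[dst] * reach[dst] for dst in LAYERS)
        dangling_parts.append(denom == 0)
        scaled = []
        for dst in LAYERS:
            frac = np.divide(
                w[dst] * reach[dst], denom, out=np.zeros_like(denom), where=denom > 0
            )
            scaled.append(sp.csr_matrix(sp.diags(frac) @ row_blocks[dst]))
        weighted_rows.append(sp.hstack(scaled, format="csr"))
    matrix = sp.vstack(weighted_rows, format="csr")
    dangling = np.concatenate(dangling_parts)
    if dangling.any():
        logger.info("%d dangling nodes (zero out-transitions)", int(dangling.sum()))
    return TransitionMatrix(
        matrix=matrix, strategy=strategy, weights=weights,
        layer_sizes=layer_sizes, dangling=dangling,
    )


def minmax_normalize(tm: TransitionMatrix) -> TransitionMatrix:
    """Min-max rescale the matrix to put its largest entry at 1.

    With the minimum taken as the structural zero of the sparse matrix, the
    transform reduces to dividing by the global maximum; the factor is stored
    in ``scale``. An all-zero matrix is returned unchanged with a warning.
    """
    m = tm.matrix
    if m.nnz == 0 or m.data.max() == 0:
        logger.warning("min-max normalization skipped: transition matrix is all zero")
        return TransitionMatrix(
            matrix=m, strategy=tm.strategy, weights=tm.weights,
            layer_sizes=tm.layer_sizes, scale=1.0, dangling=tm.dangling,
        )
    peak = float(m.data.max())
    return TransitionMatrix(
        matrix=sp.csr_matrix(m / peak), strategy=tm.strategy, weights=tm.weights,
        layer_sizes=tm.layer_sizes, scale=peak, dangling=tm.dangling,
    )


def build_transition(
    net: HeteroNetwork,
    strategy: str = "no_prior",
    weights: LayerWeights | None = None,
    normalize: bool = True,
) -> TransitionMatrix:
    """Convenience: blocks -> weighted assembly -> min-max normalization."""
    weights = weights or LayerWeights()
    tm = weight_and_assemble(build_blocks(net, strategy), weights, strategy)
    return minmax_normalize(tm) if normalize else tm
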