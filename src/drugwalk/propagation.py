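"""Random walk with restart from a drug's seed nodes.

To score how strongly each disease relates to a query drug, the walker
starts from the drug itself and its (retained) target proteins — under the
full strategy also from the diseases it is already known to treat — and
iterates

    p_{t+1} = (1 - r) M^T p_t + r p0

until the L1 change between successive iterates falls below tolerance
(default 1e-10). The disease block of the stationary vector ranks the
candidate indications: diseases holding more stationary probability are more
likely to be treatable by the drug.

Because the transition matrix is min-max rescaled rather than strictly
stochastic, the iteration contracts only while (1 - r) * sigma(M) < 1; a
growing L1 change over many consecutive iterations is therefore detected and
reported as divergence instead of looping to the iteration cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import HeteroNetwork
from .transition import LayerWeights, TransitionMatrix

__all__ = [
    "SeedProfile",
    "PropagationResult",
    "ConvergenceError",
    "build_seed",
    "propagate",
    "prioritize",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000
#: consecutive iterations of growing L1 change that trigger a divergence error
DIVERGENCE_PATIENCE = 50


class ConvergenceError(RuntimeError):
    """Raised when the restart iteration fails to reach the L1 tolerance."""

    def __init__(self, message: str, iterations: int, last_delta: float):
        super().__init__(message)
        self.iterations = iterations
        self.last_delta = last_delta


@dataclass
class SeedProfile:
    """The initial probability p0 = [a*u0; b*v0; c*h0] for a query drug.

    u0 spreads over the drug's prior-linked diseases (zero without prior
    knowledge), v0 uniformly over its retained target proteins, and h0 puts
    unit mass on the drug itself. After the layer weights are applied, the
    whole vector is renormalized to sum 1 so that drugs whose seed misses a
    layer (no targets, or no prior links) remain comparable.
    """

    drug: str
    p0: np.ndarray
    layer_sizes: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p0.shape != (sum(self.layer_sizes),):
            raise ValueError("seed vector length does not match layer sizes")
        if (self.p0 < 0).any():
            raise ValueError("seed vector has negative entries")
        if not np.isclose(self.p0.sum(), 1.0):
            raise ValueError(f"seed vector sums to {self.p0.sum()}, expected 1")

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nd, np_, _ = self.layer_sizes
        return self.p0[:nd], self.p0[nd:nd + np_], self.p0[nd + np_:]


def build_seed(
    net: HeteroNetwork,
    drug: str,
    weights: LayerWeights | None = None,
    strategy: str = "no_prior",
) -> SeedProfile:
    """Construct the seed profile for a query drug.

    h0 is a unit mass at the drug; v0 is uniform over the drug's retained
    targets (zero if it has none); u0 is zero under ``no_prior`` and uniform
    over the drug's known treated diseases under ``full``. The blocks are
    scaled by (a, b, c) and globally renormalized to sum 1, which amounts to
    renormalizing over the weights of the non-empty blocks.
    """
    weights = weights or LayerWeights()
    gi = net.drug_pos(drug)  # raises KeyError for unknown drugs
    nd, np_, ng = len(net.diseases), len(net.proteins), len(net.drugs)

    h0 = np.zeros(ng)
    h0[gi] = 1.0
    v0 = np.zeros(np_)
    target_rows = net.S2.getcol(gi).nonzero()[0]
    if target_rows.size:
        v0[target_rows] = 1.0 / target_rows.size
    u0 = np.zeros(nd)
    if strategy == "full":
        prior_cols = net.S6.getrow(gi).nonzero()[1]
        if prior_cols.size:
            u0[prior_cols] = 1.0 / prior_cols.size

    p0 = np.concatenate([weights.a * u0, weights.b * v0, weights.c * h0])
    total = p0.sum()
    if target_rows.size == 0 and not u0.any():
        logger.warning("drug %r has no retained targets and no prior links; seeding drug node only", drug)
    if total == 0.0:
        # all weighted blocks empty (e.g. c = 0 and no targets): fall back to
        # the bare drug node so the walk is still defined
        p0[nd + np_ + gi] = 1.0
        total = 1.0
    p0 /= total
    return SeedProfile(drug=drug, p0=p0, layer_sizes=(nd, np_, ng))


@dataclass
class PropagationResult:
    """Converged stationary probability with iteration diagnostics."""

    seed: SeedProfile
    p_inf: np.ndarray
    iterations: int
    final_delta: float
    restart: float

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nd, np_, _ = self.seed.layer_sizes
        return self.p_inf[:nd], self.p_inf[nd:nd + np_], self.p_inf[nd + np_:]


def propagate(
    tm: TransitionMatrix,
    seed: SeedProfile,
    r: float = 0.7,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationResult:
    """Iterate p_{t+1} = (1-r) M^T p_t + r p0 to the L1 fixed point.

    Returns the first iterate whose L1 change from its predecessor is below
    ``tol``. At r = 1 the restart dominates and p0 is returned after a single
    step. Divergence (L1 change growing for many consecutive iterations, as
    can happen when the rescaled matrix is too expansive for the chosen r) is
    reported as a :class:`ConvergenceError` carrying diagnostics.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability r={r} outside (0, 1]")
    if sum(tm.layer_sizes) != seed.p0.shape[0]:
        raise ValueError("transition matrix and seed dimensions disagree")
    mt = tm.matrix.T.tocsr()
    p0 = seed.p0
    p = p0.copy()
    growing = 0
    prev_delta = np.inf
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (mt @ p) + r * p0
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            return PropagationResult(
                seed=seed, p_inf=p, iterations=it, final_delta=delta, restart=r
            )
        growing = growing + 1 if delta > prev_delta else 0
        prev_delta = delta
        if growing >= DIVERGENCE_PATIENCE:
            raise ConvergenceError(
                f"propagation diverging: L1 change grew for {growing} consecutive "
                f"iterations (last delta {delta:.3e} at iteration {it}); "
                f"(1-r)*sigma(M) likely exceeds 1 for r={r}",
                iterations=it, last_delta=delta,
            )
    raise ConvergenceError(
        f"no convergence within {max_iter} iterations (last L1 change {prev_delta:.3e})",
        iterations=max_iter, last_delta=prev_delta,
    )


def prioritize(result: PropagationResult, net: HeteroNetwork):
    """Rank diseases by their stationary probability, highest first.

    Ties are broken lexicographically by disease ID. Returns a DataFrame with
    columns disease_id, score, rank and top_percent (rank / total * 100, the
    'Rank (%)' presentation of a prioritization).
    """
    import pandas as pd

    u_inf, _, _ = result.blocks()
    if len(u_inf) != len(net.diseases):
        raise ValueError("result and network disease layers disagree")
    order = sorted(range(len(u_inf)), key=lambda i: (-u_inf[i], net.diseases[i]))
    total = len(order)
    return pd.DataFrame(
        {
            "disease_id": [net.diseases[i] for i in order],
            "score": [float(u_inf[i]) for i in order],
            "rank": np.arange(1, total + 1),
            "top_percent": np.arange(1, total + 1) / total * 100.0,
        }
    )
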