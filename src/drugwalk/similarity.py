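"""Chemical and semantic similarity kernels.

Two intra-layer similarity matrices feed the heterogeneous network:

* drug-drug structural similarity, the Tanimoto coefficient over fixed-length
  binary substructure fingerprints (FP2-style, 1024 bits), producing S4;
* disease-disease semantic similarity, Lin's node-based information-content
  measure over a MeSH-style descriptor hierarchy, producing S5.

Both kernels return values in [0, 1], are symmetric, and equal 1 on the
diagonal of the assembled matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Fingerprint",
    "MeshHierarchy",
    "SimilarityMatrix",
    "tanimoto",
    "drug_similarity_matrix",
    "lin_similarity",
    "disease_similarity_matrix",
]

logger = logging.getLogger(__name__)

FINGERPRINT_LENGTH = 1024


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary substructure fingerprint for one drug.

    ``bits`` is a boolean vector; FP2-style fingerprints are 1024 bits long but
    any constant length is accepted as long as it is consistent within a set.
    An all-zero fingerprint is allowed (e.g. a molecule with no indexable
    substructure) but is flagged in the log because it carries no structural
    information.
    """

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", arr)
        if arr.ndim != 1:
            raise ValueError(f"fingerprint bits must be a 1-D vector, got shape {arr.shape}")
        if not arr.any():
            logger.warning("fingerprint for drug %r has no bits set", self.drug_id)

    def __len__(self) -> int:
        return int(self.bits.shape[0])

    @classmethod
    def from_bitstring(cls, drug_id: str, bitstring: str) -> "Fingerprint":
        """Parse a '0'/'1' character string into a fingerprint."""
        if set(bitstring) - {"0", "1"}:
            raise ValueError(f"bitstring for {drug_id!r} contains characters other than 0/1")
        return cls(drug_id, np.frombuffer(bitstring.encode(), dtype=np.uint8) == ord("1"))

    @classmethod
    def from_hex(cls, drug_id: str, hexstring: str, n_bits: int = FINGERPRINT_LENGTH) -> "Fingerprint":
        """Parse a hex-encoded fingerprint (most-significant bit first)."""
        raw = bytes.fromhex(hexstring)
        bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))[:n_bits]
        return cls(drug_id, bits.astype(bool))


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient: common bits divided by the union of the bit sets.

    Defined as 0 when both fingerprints are all-zero (no evidence of
    similarity either way); that degenerate case is logged.
    """
    if len(fp_a) != len(fp_b):
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.drug_id!r} has {len(fp_a)} bits, "
            f"{fp_b.drug_id!r} has {len(fp_b)}"
        )
    union = int(np.count_nonzero(fp_a.bits | fp_b.bits))
    if union == 0:
        logger.warning(
            "tanimoto(%r, %r): both fingerprints empty, similarity defined as 0",
            fp_a.drug_id, fp_b.drug_id,
        )
        return 0.0
    common = int(np.count_nonzero(fp_a.bits & fp_b.bits))
    return common / union


@dataclass
class SimilarityMatrix:
    """A symmetric similarity matrix over an ordered set of node IDs.

    Values lie in [0, 1]; the diagonal is 1 (self-similarity). Used for both
    the drug layer (S4) and the disease layer (S5).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("similarity values outside [0, 1]")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        self._pos = {i: k for k, i in enumerate(self.ids)}

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    def subset(self, ids: list[str] | tuple[str, ...]) -> "SimilarityMatrix":
        """Restrict to a subset of ids, keeping the given order."""
        missing = [i for i in ids if i not in self._pos]
        if missing:
            raise KeyError(f"ids absent from similarity matrix: {missing[:5]}")
        idx = [self._pos[i] for i in ids]
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def __contains__(self, id_: str) -> bool:
        return id_ in self._pos


def drug_similarity_matrix(fps: list[Fingerprint] | tuple[Fingerprint, ...]) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity over a set of drug fingerprints.

    Drug order in the matrix is the order of ``fps``. Duplicate drug IDs are
    rejected. The diagonal is forced to 1 even for all-zero fingerprints, by
    the self-similarity convention of the assembled matrices.
    """
    fps = list(fps)
    if not fps:
        raise ValueError("empty fingerprint set")
    ids = [fp.drug_id for fp in fps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate drug IDs: {dupes}")
    lengths = {len(fp) for fp in fps}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")

    # Stack and use matrix products: |a & b| = B B^T over 0/1 rows.
    bits = np.stack([fp.bits for fp in fps]).astype(np.int64)
    inter = bits @ bits.T
    pops = bits.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(ids), sim)


class MeshHierarchy:
    """A MeSH-style hierarchy: descriptors placed at dot-delimited tree numbers.

    A tree number such as ``C04.588.33`` encodes a position; its parent is the
    position with the last dot-segment removed (``C04.588``), and top-level
    segments (``C04``) are roots. A descriptor may occupy several positions.
    Information content of a position ``t`` is ``-log p(t)`` with
    ``p(t) = (number of descriptors at or below t) / (total descriptors)``.
    """

    def __init__(self, tree_numbers: dict[str, set[str] | list[str] | tuple[str, ...]]):
        if not tree_numbers:
            raise ValueError("empty hierarchy")
        self.tree_numbers: dict[str, tuple[str, ...]] = {
            d: tuple(sorted(set(tns))) for d, tns in tree_numbers.items()
        }
        positions = {tn for tns in self.tree_numbers.values() for tn in tns}
        for d, tns in self.tree_numbers.items():
            if not tns:
                raise ValueError(f"descriptor {d!r} has no tree number")
        for tn in positions:
            parent = tn.rsplit(".", 1)[0] if "." in tn else None
            if parent is not None and parent not in positions:
                raise ValueError(
                    f"tree number {tn!r} has no parent position {parent!r} in the hierarchy"
                )
        self.n_descriptors = len(self.tree_numbers)
        # descendant count (inclusive) per position prefix, counting descriptors once
        self._desc_count: dict[str, int] = {}
        prefix_members: dict[str, set[str]] = {}
        for d, tns in self.tree_numbers.items():
            for tn in tns:
                parts = tn.split(".")
                for k in range(1, len(parts) + 1):
                    prefix_members.setdefault(".".join(parts[:k]), set()).add(d)
        self._desc_count = {p: len(m) for p, m in prefix_members.items()}

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self.tree_numbers

    def information_content(self, position: str) -> float:
        """IC of a tree position: -log of its inclusive descendant frequency."""
        count = self._desc_count.get(position)
        if count is None:
            raise KeyError(f"unknown tree position {position!r}")
        return -math.log(count / self.n_descriptors)


def _lin_over_positions(hier: MeshHierarchy, pos_a: str, pos_b: str) -> float:
    ic_a = hier.information_content(pos_a)
    ic_b = hier.information_content(pos_b)
    if ic_a + ic_b == 0.0:
        return 0.0  # both positions cover every descriptor (roots)
    parts_a, parts_b = pos_a.split("."), pos_b.split(".")
    k = 0
    while k < min(len(parts_a), len(parts_b)) and parts_a[k] == parts_b[k]:
        k += 1
    if k == 0:
        return 0.0  # no common ancestor below the (virtual) root, IC 0
    ic_anc = hier.information_content(".".join(parts_a[:k]))
    return 2.0 * ic_anc / (ic_a + ic_b)


def lin_similarity(term_a: str, term_b: str, hierarchy: MeshHierarchy) -> float:
    """Lin's node-based semantic similarity between two descriptors.

    sim(a, b) = 2 IC(mica) / (IC(a) + IC(b)) where *mica* is the
    most-informative common ancestor position. Descriptors with several tree
    numbers take the maximum over tree-position pairs (the most favourable
    placement). A term compared with itself yields 1 whenever its IC is
    positive; two root terms (IC 0) yield 0.
    """
    for t in (term_a, term_b):
        if t not in hierarchy:
            raise KeyError(f"unknown descriptor {t!r}")
    best = 0.0
    for pa in hierarchy.tree_numbers[term_a]:
        for pb in hierarchy.tree_numbers[term_b]:
            best = max(best, _lin_over_positions(hierarchy, pa, pb))
    return best


def disease_similarity_matrix(
    terms: list[str] | tuple[str, ...], hierarchy: MeshHierarchy
) -> SimilarityMatrix:
    """Pairwise Lin similarity over disease descriptors; diagonal forced to 1."""
    terms = list(terms)
    if not terms:
        raise ValueError("empty term set")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate disease descriptors")
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = lin_similarity(terms[i], terms[j], hierarchy)
    return SimilarityMatrix(tuple(terms), sim)
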