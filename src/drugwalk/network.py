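"""Assembly of the heterogeneous drug-protein-disease network.

The network couples three node layers through six adjacency matrices:

====  ===================  =========================================
S1    disease x protein    1 where the disease has a verified gene
S2    protein x drug       1 where the protein is a target of the drug
S3    protein x protein    interaction confidence score (symmetric)
S4    drug x drug          chemical (Tanimoto) similarity
S5    disease x disease    semantic (Lin) similarity
S6    drug x disease       1 for a known treatment relationship (prior)
====  ===================  =========================================

Before assembly the protein layer is pruned: only proteins lying on a
disease-drug path with fewer than three protein nodes are kept, because a
random walker is unlikely to traverse longer protein chains against the dense
interaction background. Diseases and drugs left without any retained protein
neighbour are dropped as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .similarity import SimilarityMatrix

__all__ = [
    "EdgeTable",
    "PruneReport",
    "HeteroNetwork",
    "load_edges",
    "prune",
    "assemble",
]

logger = logging.getLogger(__name__)

EDGE_KINDS = ("disease_gene", "drug_target", "ppi", "drug_disease")
#: (source column, target column) semantics per edge kind
_KIND_COLUMNS = {
    "disease_gene": ("disease_id", "protein_id"),
    "drug_target": ("drug_id", "protein_id"),
    "ppi": ("protein_a", "protein_b"),
    "drug_disease": ("drug_id", "disease_id"),
}


@dataclass
class EdgeTable:
    """A typed, weighted edge list between two node layers (or within one)."""

    kind: str
    edges: pd.DataFrame  # columns: source, target, weight

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}; expected one of {EDGE_KINDS}")
        df = self.edges
        for col in ("source", "target", "weight"):
            if col not in df.columns:
                raise ValueError(f"edge table missing column {col!r}")
        if df.empty:
            raise ValueError(f"{self.kind} edge table is empty")
        if (df["weight"] < 0).any():
            bad = df[df["weight"] < 0].iloc[0]
            raise ValueError(
                f"{self.kind}: negative weight {bad['weight']} on edge "
                f"{bad['source']!r}-{bad['target']!r}"
            )
        if df["source"].eq("").any() or df["target"].eq("").any():
            raise ValueError(f"{self.kind}: empty node ID")
        if self.kind != "ppi" and (df["source"] == df["target"]).any():
            raise ValueError(f"{self.kind}: self-loop in a bipartite relation")

    def __len__(self) -> int:
        return len(self.edges)

    def sources(self) -> set[str]:
        return set(self.edges["source"])

    def targets(self) -> set[str]:
        return set(self.edges["target"])

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))


def load_edges(path: str | Path, kind: str) -> EdgeTable:
    """Read a TSV edge list (``id_a<TAB>id_b[<TAB>weight]``) as an EdgeTable.

    Binary relations default to weight 1; a third column (the interaction
    confidence for PPI data) overrides it. Duplicate edges collapse to the
    maximum weight; for the undirected kinds (ppi) the pair is canonicalised
    before collapsing. Malformed rows are reported with their line number.
    """
    path = Path(path)
    if kind not in EDGE_KINDS:
        raise ValueError(f"unknown edge kind {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node ID")
            w = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            rows.append((a, b, w))
    if not rows:
        raise ValueError(f"{path}: no edges found")
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    if kind == "ppi":
        lo = df[["source", "target"]].min(axis=1)
        hi = df[["source", "target"]].max(axis=1)
        df["source"], df["target"] = lo, hi
    df = df.groupby(["source", "target"], as_index=False)["weight"].max()
    return EdgeTable(kind, df)


@dataclass
class PruneReport:
    """Outcome of the short-path pruning rule.

    ``direct_bridge_proteins`` are retained as the single protein of a
    disease-protein-drug path; ``ppi_bridge_proteins`` are retained through a
    two-protein path disease-p-q-drug. The two sets may overlap.
    """

    retained_proteins: set[str]
    removed_proteins: set[str]
    removed_diseases: set[str]
    removed_drugs: set[str]
    direct_bridge_proteins: set[str] = field(default_factory=set)
    ppi_bridge_proteins: set[str] = field(default_factory=set)

    @property
    def n_one_protein_paths(self) -> int:
        return len(self.direct_bridge_proteins)

    @property
    def n_two_protein_paths(self) -> int:
        return len(self.ppi_bridge_proteins)


def prune(
    disease_gene: EdgeTable,
    drug_target: EdgeTable,
    ppi: EdgeTable | None,
) -> PruneReport:
    """Keep proteins on disease-drug paths with fewer than three proteins.

    A protein is retained iff it lies on a path
    ``disease - p - drug`` (one protein) or ``disease - p - q - drug``
    (two proteins linked by a PPI edge); both endpoints of a qualifying PPI
    bridge are retained. Diseases with no retained associated protein and
    drugs with no retained target are reported as removed.
    """
    disease_assoc: dict[str, set[str]] = {}
    for d, p in disease_gene.pairs():
        disease_assoc.setdefault(p, set()).add(d)
    target_of: dict[str, set[str]] = {}
    for g, p in drug_target.pairs():
        target_of.setdefault(p, set()).add(g)

    all_proteins = set(disease_assoc) | set(target_of)
    direct = set(disease_assoc) & set(target_of)

    ppi_bridged: set[str] = set()
    if ppi is not None:
        for p, q in ppi.pairs():
            if p == q:
                continue
            all_proteins.update((p, q))
            # disease - p - q - drug, in either orientation
            if p in disease_assoc and q in target_of:
                ppi_bridged.update((p, q))
            if q in disease_assoc and p in target_of:
                ppi_bridged.update((p, q))

    retained = direct | ppi_bridged
    removed_proteins = all_proteins - retained
    removed_diseases = {
        d for d in disease_gene.sources()
        if not any(p in retained for p in _assoc_proteins(disease_gene, d))
    }
    removed_drugs = {
        g for g in drug_target.sources()
        if not any(p in retained for p in _assoc_proteins(drug_target, g))
    }
    logger.info(
        "prune: retained %d/%d proteins (%d direct, %d via PPI bridge); "
        "removed %d diseases, %d drugs",
        len(retained), len(all_proteins), len(direct), len(ppi_bridged),
        len(removed_diseases), len(removed_drugs),
    )
    return PruneReport(
        retained_proteins=retained,
        removed_proteins=removed_proteins,
        removed_diseases=removed_diseases,
        removed_drugs=removed_drugs,
        direct_bridge_proteins=direct,
        ppi_bridge_proteins=ppi_bridged,
    )


def _assoc_proteins(table: EdgeTable, source_id: str) -> set[str]:
    df = table.edges
    return set(df.loc[df["source"] == source_id, "target"])


@dataclass
class HeteroNetwork:
    """The assembled multilayer network over consistent, sorted node indices."""

    diseases: tuple[str, ...]
    proteins: tuple[str, ...]
    drugs: tuple[str, ...]
    S1: sp.csr_matrix  # disease x protein, 0/1
    S2: sp.csr_matrix  # protein x drug, 0/1
    S3: sp.csr_matrix  # protein x protein, symmetric scores
    S4: np.ndarray     # drug x drug similarity
    S5: np.ndarray     # disease x disease similarity
    S6: sp.csr_matrix  # drug x disease, 0/1
    prune_report: PruneReport | None = None

    def __post_init__(self) -> None:
        nd, np_, ng = len(self.diseases), len(self.proteins), len(self.drugs)
        expected = {
            "S1": (nd, np_), "S2": (np_, ng), "S3": (np_, np_),
            "S4": (ng, ng), "S5": (nd, nd), "S6": (ng, nd),
        }
        for name, shape in expected.items():
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
        self._disease_pos = {d: i for i, d in enumerate(self.diseases)}
        self._protein_pos = {p: i for i, p in enumerate(self.proteins)}
        self._drug_pos = {g: i for i, g in enumerate(self.drugs)}

    @property
    def n_nodes(self) -> int:
        return len(self.diseases) + len(self.proteins) + len(self.drugs)

    def disease_pos(self, d: str) -> int:
        return self._disease_pos[d]

    def drug_pos(self, g: str) -> int:
        if g not in self._drug_pos:
            raise KeyError(f"drug {g!r} not in network")
        return self._drug_pos[g]

    def drug_targets(self, drug: str) -> tuple[str, ...]:
        """Retained target proteins of a drug, in protein-index order."""
        col = self.S2.getcol(self.drug_pos(drug))
        return tuple(self.proteins[i] for i in sorted(col.nonzero()[0]))

    def drug_prior_diseases(self, drug: str) -> tuple[str, ...]:
        """Diseases linked to a drug through the prior-knowledge matrix S6."""
        row = self.S6.getrow(self.drug_pos(drug))
        return tuple(self.diseases[i] for i in sorted(row.nonzero()[1]))

    def with_s6(self, s6: sp.spmatrix) -> "HeteroNetwork":
        """Copy of the network with a replacement prior-knowledge matrix."""
        return HeteroNetwork(
            self.diseases, self.proteins, self.drugs,
            self.S1, self.S2, self.S3, self.S4, self.S5,
            sp.csr_matrix(s6), self.prune_report,
        )


def assemble(
    disease_gene: EdgeTable,
    drug_target: EdgeTable,
    ppi: EdgeTable | None,
    drug_disease: EdgeTable | None,
    s4: SimilarityMatrix,
    s5: SimilarityMatrix,
    prune_report: PruneReport,
    include_prior: bool = False,
    ppi_score_cutoff: float = 0.0,
    similarity_cutoff: float = 0.0,
) -> HeteroNetwork:
    """Build the six adjacency matrices restricted to the retained nodes.

    Node order is lexicographic by ID within each layer so that every
    downstream matrix is reproducible. Drugs without a row in the chemical
    similarity matrix are excluded with a warning (mirroring the availability
    filter applied when fingerprints cannot be computed); diseases without a
    semantic similarity row likewise. S6 stays empty unless ``include_prior``.

    No thresholds are applied by default; ``ppi_score_cutoff`` zeroes S3
    entries below it (interaction-confidence filtering, as STRING users
    customarily do) and ``similarity_cutoff`` does the same for the
    off-diagonal entries of S4 and S5.
    """
    retained = prune_report.retained_proteins
    if not retained:
        raise ValueError("pruning retained no proteins; network would be empty")

    diseases = {
        d for d, p in disease_gene.pairs() if p in retained
    } - prune_report.removed_diseases
    drugs = {
        g for g, p in drug_target.pairs() if p in retained
    } - prune_report.removed_drugs

    dropped_drugs = sorted(g for g in drugs if g not in s4)
    if dropped_drugs:
        logger.warning(
            "excluding %d drugs without a chemical-similarity row: %s",
            len(dropped_drugs), dropped_drugs[:5],
        )
        drugs -= set(dropped_drugs)
    dropped_dis = sorted(d for d in diseases if d not in s5)
    if dropped_dis:
        logger.warning(
            "excluding %d diseases without a semantic-similarity row: %s",
            len(dropped_dis), dropped_dis[:5],
        )
        diseases -= set(dropped_dis)
    if not diseases or not drugs:
        raise ValueError("no diseases or no drugs remain after assembly filters")

    disease_ids = tuple(sorted(diseases))
    protein_ids = tuple(sorted(retained))
    drug_ids = tuple(sorted(drugs))
    dpos = {d: i for i, d in enumerate(disease_ids)}
    ppos = {p: i for i, p in enumerate(protein_ids)}
    gpos = {g: i for i, g in enumerate(drug_ids)}

    def bipartite(table: EdgeTable, rows: dict, cols: dict, shape) -> sp.csr_matrix:
        r, c, v = [], [], []
        for (a, b), w in zip(
            zip(table.edges["source"], table.edges["target"]), table.edges["weight"]
        ):
            if a in rows and b in cols:
                r.append(rows[a]); c.append(cols[b]); v.append(w)
        return sp.csr_matrix((v, (r, c)), shape=shape)

    s1 = bipartite(disease_gene, dpos, ppos, (len(disease_ids), len(protein_ids)))
    s1.data[:] = 1.0  # verified relationship is binary
    s2t = bipartite(drug_target, gpos, ppos, (len(drug_ids), len(protein_ids)))
    s2t.data[:] = 1.0
    s2 = sp.csr_matrix(s2t.T)

    if ppi is not None:
        r, c, v = [], [], []
        for a, b, w in ppi.edges[["source", "target", "weight"]].itertuples(index=False):
            if a in ppos and b in ppos and a != b:
                r += [ppos[a], ppos[b]]
                c += [ppos[b], ppos[a]]
                v += [w, w]
        s3 = sp.csr_matrix((v, (r, c)), shape=(len(protein_ids),) * 2)
        s3 = s3.maximum(s3.T)  # enforce symmetry under duplicate listings
        if ppi_score_cutoff > 0.0:
            s3.data[s3.data < ppi_score_cutoff] = 0.0
            s3.eliminate_zeros()
    else:
        s3 = sp.csr_matrix((len(protein_ids),) * 2)

    s4m = s4.subset(drug_ids).values
    s5m = s5.subset(disease_ids).values
    if similarity_cutoff > 0.0:
        for m in (s4m, s5m):
            diag = np.diag(m).copy()
            m[m < similarity_cutoff] = 0.0
            np.fill_diagonal(m, diag)

    if include_prior and drug_disease is not None:
        s6 = bipartite(drug_disease, gpos, dpos, (len(drug_ids), len(disease_ids)))
        s6.data[:] = 1.0
    else:
        s6 = sp.csr_matrix((len(drug_ids), len(disease_ids)))

    return HeteroNetwork(
        disease_ids, protein_ids, drug_ids, s1, s2, s3, s4m, s5m, s6,
        prune_report=prune_report,
    )
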