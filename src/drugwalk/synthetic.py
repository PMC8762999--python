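"""Synthetic multilayer inputs with a planted drug-disease signal.

The generator emulates the structure of the real inputs — disease-gene,
drug-target and protein-protein edge tables, FP2-style fingerprints, a
MeSH-style hierarchy, and a validation set of drug-disease pairs — at toy
scale, so every stage of the pipeline can be exercised without any database
download. Background edges are independent Bernoulli draws at the configured
densities. For each planted (drug, disease) pair, the drug's target set and
the disease's gene set are forced to share proteins (a fraction ``signal``
of the smaller set, at least one protein when ``signal > 0``), so a short
disease-protein-drug path exists and the walk can recover the pair;
fingerprints of planted drugs share a common bit block proportional to
``signal``. At ``signal = 0`` the planted pairs are statistically
indistinguishable from the background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ValidationSet
from .network import EdgeTable
from .similarity import FINGERPRINT_LENGTH, Fingerprint, MeshHierarchy

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "make_validation"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults describe a small but non-degenerate multilayer network: three
    node layers at toy scale, sparse background association densities, five
    treatable (drug, disease) pairs planted with strong (0.8) target/gene
    overlap, and a couple of bits set per ~100 fingerprint positions.
    """

    n_diseases: int = 20
    n_proteins: int = 60
    n_drugs: int = 15
    disease_gene_density: float = 0.05
    drug_target_density: float = 0.05
    ppi_density: float = 0.05
    n_planted: int = 5
    signal: float = 0.8
    fingerprint_bits: int = FINGERPRINT_LENGTH
    fingerprint_density: float = 0.02
    n_hierarchy_roots: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disease_gene_density", "drug_target_density", "ppi_density",
                     "signal", "fingerprint_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_planted > self.n_drugs:
            raise ValueError("more planted pairs than drugs")
        if self.n_planted > self.n_diseases:
            raise ValueError("more planted pairs than diseases")
        if min(self.n_diseases, self.n_proteins, self.n_drugs) < 1:
            raise ValueError("layer sizes must be positive")
        # a planted pair needs at least one shared protein
        if self.signal > 0 and self.n_proteins < 1:
            raise ValueError("signal requires at least one protein")


@dataclass
class SyntheticBundle:
    """Generated inputs plus the planted ground truth."""

    spec: SyntheticSpec
    disease_gene: EdgeTable
    drug_target: EdgeTable
    ppi: EdgeTable
    drug_disease: EdgeTable | None
    fingerprints: list[Fingerprint]
    hierarchy: MeshHierarchy
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def write(self, outdir: str | Path) -> Path:
        """Serialize the bundle in the exact TSV formats the loaders read."""
        from . import io as dwio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dwio.write_edges(self.disease_gene, outdir / "disease_gene.tsv")
        dwio.write_edges(self.drug_target, outdir / "drug_target.tsv")
        dwio.write_edges(self.ppi, outdir / "ppi.tsv")
        if self.drug_disease is not None:
            dwio.write_edges(self.drug_disease, outdir / "drug_disease.tsv")
        dwio.write_fingerprints(self.fingerprints, outdir / "fingerprints.tsv")
        dwio.write_hierarchy(self.hierarchy, outdir / "mesh_tree.tsv")
        pd.DataFrame(self.planted_pairs, columns=["drug_id", "disease_id"]).to_csv(
            outdir / "planted_pairs.tsv", sep="\t", index=False
        )
        manifest = {"spec": asdict(self.spec)}
        import json

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return outdir


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw a complete input bundle under the given study conditions.

    All randomness flows from ``spec.seed``; identical specs give identical
    bundles. The planted pairs are chosen as (drug i, disease i) for the
    first ``n_planted`` indices after an id shuffle, and each is wired with
    ``ceil(signal * min(|targets|, |genes|))`` shared proteins (minimum one
    while signal > 0) plus a prior-knowledge edge in the drug-disease table.
    """
    rng = np.random.default_rng(spec.seed)
    diseases = _ids("MESHD", spec.n_diseases)
    proteins = _ids("P", spec.n_proteins)
    drugs = _ids("DB", spec.n_drugs)

    def bernoulli_edges(rows, cols, density, no_self=False):
        mask = rng.random((len(rows), len(cols))) < density
        out = []
        for i, a in enumerate(rows):
            for j, b in enumerate(cols):
                if mask[i, j] and not (no_self and a == b):
                    out.append((a, b))
        return out

    dg_edges = set(bernoulli_edges(diseases, proteins, spec.disease_gene_density))
    dt_edges = set(bernoulli_edges(drugs, proteins, spec.drug_target_density))
    ppi_pairs = set()
    for i in range(spec.n_proteins):
        for j in range(i + 1, spec.n_proteins):
            if rng.random() < spec.ppi_density:
                ppi_pairs.add((proteins[i], proteins[j]))

    planted_drugs = list(rng.choice(drugs, size=spec.n_planted, replace=False))
    planted_diseases = list(rng.choice(diseases, size=spec.n_planted, replace=False))
    planted = list(zip(planted_drugs, planted_diseases))

    if spec.signal > 0:
        for g, d in planted:
            tgts = {p for gg, p in dt_edges if gg == g}
            genes = {p for dd, p in dg_edges if dd == d}
            k = max(1, math.ceil(spec.signal * max(1, min(len(tgts), len(genes)))))
            k = min(k, spec.n_proteins)
            shared = rng.choice(proteins, size=k, replace=False)
            for p in shared:
                dt_edges.add((g, p))
                dg_edges.add((d, p))

    # every node appears at least once so the layers are fully populated
    for d in diseases:
        if not any(dd == d for dd, _ in dg_edges):
            dg_edges.add((d, str(rng.choice(proteins))))
    for g in drugs:
        if not any(gg == g for gg, _ in dt_edges):
            dt_edges.add((g, str(rng.choice(proteins))))
    if not ppi_pairs:
        ppi_pairs.add((proteins[0], proteins[min(1, spec.n_proteins - 1)]))

    def table(kind, pairs, weights=None):
        df = pd.DataFrame(sorted(pairs), columns=["source", "target"])
        if weights is None:
            df["weight"] = 1.0
        else:
            df["weight"] = weights(len(df))
        return EdgeTable(kind, df)

    disease_gene = table("disease_gene", dg_edges)
    drug_target = table("drug_target", dt_edges)
    ppi = table("ppi", ppi_pairs, weights=lambda n: np.round(rng.uniform(0.15, 1.0, n), 3))
    drug_disease = table("drug_disease", set(planted)) if planted else None

    # fingerprints: sparse random bits; planted drugs share a signal block
    n_set = max(4, int(spec.fingerprint_bits * spec.fingerprint_density))
    shared_block = rng.choice(spec.fingerprint_bits, size=n_set, replace=False)
    n_shared = int(round(spec.signal * n_set))
    fingerprints = []
    for g in drugs:
        bits = np.zeros(spec.fingerprint_bits, dtype=bool)
        own = rng.choice(spec.fingerprint_bits, size=n_set, replace=False)
        bits[own] = True
        if g in planted_drugs and n_shared:
            bits[shared_block[:n_shared]] = True
        fingerprints.append(Fingerprint(g, bits))

    # two-level MeSH-style tree: roots C01.. with diseases under random roots
    roots = [f"C{i:02d}" for i in range(1, spec.n_hierarchy_roots + 1)]
    tree_numbers: dict[str, set[str]] = {f"ROOT{r}": {r} for r in roots}
    for idx, d in enumerate(diseases):
        root = roots[int(rng.integers(len(roots)))]
        tree_numbers[d] = {f"{root}.{idx + 1:03d}"}
    hierarchy = MeshHierarchy(tree_numbers)

    return SyntheticBundle(
        spec=spec,
        disease_gene=disease_gene,
        drug_target=drug_target,
        ppi=ppi,
        drug_disease=drug_disease,
        fingerprints=fingerprints,
        hierarchy=hierarchy,
        planted_pairs=planted,
    )


def make_validation(
    bundle: SyntheticBundle, n_folds: int = 0
) -> ValidationSet:
    """Planted pairs as validation positives, fold labels round-robin."""
    if not bundle.planted_pairs:
        raise ValueError("bundle has no planted pairs")
    df = pd.DataFrame(bundle.planted_pairs, columns=["drug_id", "disease_id"])
    if n_folds:
        df["fold"] = np.arange(len(df)) % n_folds + 1
    return ValidationSet(df)
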