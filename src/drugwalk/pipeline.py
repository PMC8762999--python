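"""End-to-end conveniences: inputs -> network -> transition -> rankings."""

from __future__ import annotations

from pathlib import Path

from .network import EdgeTable, HeteroNetwork, assemble, load_edges, prune
from .similarity import (
    Fingerprint,
    MeshHierarchy,
    disease_similarity_matrix,
    drug_similarity_matrix,
)

__all__ = ["network_from_tables", "network_from_bundle", "network_from_dir"]


def network_from_tables(
    disease_gene: EdgeTable,
    drug_target: EdgeTable,
    ppi: EdgeTable | None,
    drug_disease: EdgeTable | None,
    fingerprints: list[Fingerprint],
    hierarchy: MeshHierarchy,
    include_prior: bool = False,
) -> HeteroNetwork:
    """Prune, compute both similarity kernels, and assemble the network."""
    report = prune(disease_gene, drug_target, ppi)
    s4 = drug_similarity_matrix(fingerprints)
    disease_ids = sorted(
        d for d in disease_gene.sources()
        if d not in report.removed_diseases and d in hierarchy
    )
    s5 = disease_similarity_matrix(disease_ids, hierarchy)
    return assemble(
        disease_gene, drug_target, ppi, drug_disease, s4, s5, report,
        include_prior=include_prior,
    )


def network_from_bundle(bundle, include_prior: bool = False) -> HeteroNetwork:
    """Assemble a network straight from a synthetic bundle."""
    return network_from_tables(
        bundle.disease_gene, bundle.drug_target, bundle.ppi, bundle.drug_disease,
        bundle.fingerprints, bundle.hierarchy, include_prior=include_prior,
    )


def network_from_dir(indir: str | Path, include_prior: bool = False) -> HeteroNetwork:
    """Assemble a network from a directory of input files.

    Expects disease_gene.tsv, drug_target.tsv, fingerprints.tsv and
    mesh_tree.tsv; ppi.tsv and drug_disease.tsv are optional.
    """
    from . import io as dwio

    indir = Path(indir)
    disease_gene = load_edges(indir / "disease_gene.tsv", "disease_gene")
    drug_target = load_edges(indir / "drug_target.tsv", "drug_target")
    ppi = (
        load_edges(indir / "ppi.tsv", "ppi") if (indir / "ppi.tsv").exists() else None
    )
    drug_disease = (
        load_edges(indir / "drug_disease.tsv", "drug_disease")
        if (indir / "drug_disease.tsv").exists()
        else None
    )
    fps = dwio.read_fingerprints(indir / "fingerprints.tsv")
    hierarchy = dwio.read_hierarchy(indir / "mesh_tree.tsv")
    return network_from_tables(
        disease_gene, drug_target, ppi, drug_disease, fps, hierarchy,
        include_prior=include_prior,
    )
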