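"""Readers and writers for the plain-text interchange formats.

Everything is TSV or MatrixMarket coordinate text: edge lists, fingerprint
tables (binary or hex encoded, auto-detected), MeSH-style hierarchy exports
(one descriptor/tree-number row per line), precomputed similarity tables,
and the serialized network/transition bundles with a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .network import EdgeTable, HeteroNetwork
from .similarity import Fingerprint, MeshHierarchy, SimilarityMatrix

__all__ = [
    "read_fingerprints",
    "write_fingerprints",
    "read_hierarchy",
    "write_hierarchy",
    "read_similarity_table",
    "write_similarity_table",
    "write_edges",
    "write_network",
    "read_network",
]

_HEX_CHARS = set("0123456789abcdefABCDEF")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read a TSV of drug_id<TAB>fingerprint rows.

    The encoding is auto-detected from the character set: strings of only
    0/1 whose length is not a power-of-two fraction of pure hex are treated
    as bitstrings, anything else hex. A header row is tolerated.
    """
    path = Path(path)
    fps: list[Fingerprint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected drug_id<TAB>fingerprint")
            drug_id, payload = parts[0].strip(), parts[1].strip()
            if lineno == 1 and payload.lower() in {"bitstring", "fingerprint", "bits"}:
                continue
            if set(payload) <= {"0", "1"}:
                fps.append(Fingerprint.from_bitstring(drug_id, payload))
            elif set(payload) <= _HEX_CHARS:
                fps.append(Fingerprint.from_hex(drug_id, payload))
            else:
                raise ValueError(f"{path}:{lineno}: fingerprint is neither binary nor hex")
    if not fps:
        raise ValueError(f"{path}: no fingerprints found")
    return fps


def write_fingerprints(fps: list[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fp in fps:
            bits = "".join("1" if b else "0" for b in fp.bits)
            fh.write(f"{fp.drug_id}\t{bits}\n")


def read_hierarchy(path: str | Path) -> MeshHierarchy:
    """Read a TSV of descriptor_id<TAB>tree_number rows (one per tree number)."""
    path = Path(path)
    tree_numbers: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected descriptor_id<TAB>tree_number")
            desc, tn = parts[0].strip(), parts[1].strip()
            if lineno == 1 and tn.lower() == "tree_number":
                continue
            tree_numbers.setdefault(desc, set()).add(tn)
    return MeshHierarchy(tree_numbers)


def write_hierarchy(hierarchy: MeshHierarchy, path: str | Path) -> None:
    with open(path, "w") as fh:
        for desc in sorted(hierarchy.tree_numbers):
            for tn in hierarchy.tree_numbers[desc]:
                fh.write(f"{desc}\t{tn}\n")


def read_similarity_table(path: str | Path, ids: list[str] | None = None) -> SimilarityMatrix:
    """Read a precomputed (id_a, id_b, value) TSV as a similarity matrix.

    Accepted in place of either kernel. Missing pairs default to 0, the
    diagonal to 1; the table may list each unordered pair once.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["id_a", "id_b", "value"],
                     dtype={"id_a": str, "id_b": str}, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty similarity table")
    if ids is None:
        ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    m = np.eye(n)
    for a, b, v in df.itertuples(index=False):
        if a in pos and b in pos:
            m[pos[a], pos[b]] = v
            m[pos[b], pos[a]] = v
    return SimilarityMatrix(tuple(ids), m)


def write_similarity_table(sim: SimilarityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(sim.ids):
            for j in range(i + 1, len(sim.ids)):
                v = sim.values[i, j]
                if v != 0.0:
                    fh.write(f"{a}\t{sim.ids[j]}\t{v:.10g}\n")


def write_edges(table: EdgeTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False, header=False,
                       columns=["source", "target", "weight"])


def _write_matrix(m, path: Path) -> None:
    mmwrite(str(path), sp.coo_matrix(m))


def write_network(net: HeteroNetwork, outdir: str | Path) -> Path:
    """Serialize the network as MatrixMarket files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("S1", "S2", "S3", "S4", "S5", "S6"):
        _write_matrix(getattr(net, name), outdir / f"{name}.mtx")
    manifest = {
        "diseases": list(net.diseases),
        "proteins": list(net.proteins),
        "drugs": list(net.drugs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def read_network(indir: str | Path) -> HeteroNetwork:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    mats = {
        name: mmread(str(indir / f"{name}.mtx")) for name in ("S1", "S2", "S3", "S4", "S5", "S6")
    }
    return HeteroNetwork(
        tuple(manifest["diseases"]),
        tuple(manifest["proteins"]),
        tuple(manifest["drugs"]),
        sp.csr_matrix(mats["S1"]),
        sp.csr_matrix(mats["S2"]),
        sp.csr_matrix(mats["S3"]),
        np.asarray(sp.coo_matrix(mats["S4"]).todense()),
        np.asarray(sp.coo_matrix(mats["S5"]).todense()),
        sp.csr_matrix(mats["S6"]),
    )
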