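"""Pruning the protein layer and assembling the six adjacency matrices.

A protein survives only if it sits on a disease-drug path with at most two
protein nodes: either it is both disease-associated and a drug target, or a
single interaction edge connects it to a partner that completes such a path.
"""

import numpy as np
import pandas as pd

from drugwalk import EdgeTable, SimilarityMatrix, assemble, prune


def table(kind, pairs, weights=None):
    df = pd.DataFrame(pairs, columns=["source", "target"])
    df["weight"] = weights if weights is not None else 1.0
    return EdgeTable(kind, df)


disease_gene = table("disease_gene", [("D1", "P1"), ("D1", "P4")])
drug_target = table("drug_target", [("G1", "P2")])
ppi = table("ppi", [("P1", "P2"), ("P3", "P4")], weights=[0.8, 0.6])

report = prune(disease_gene, drug_target, ppi)
print("retained proteins:", sorted(report.retained_proteins))
print("removed proteins: ", sorted(report.removed_proteins))
# P1-P2 bridges D1 to G1 (a two-protein path), so both survive; P3 and P4
# reach no drug within two protein hops and are dropped.

s4 = SimilarityMatrix(("G1",), np.array([[1.0]]))
s5 = SimilarityMatrix(("D1",), np.array([[1.0]]))
net = assemble(disease_gene, drug_target, ppi, None, s4, s5, report)
print("S1 (disease x protein):")
print(net.S1.toarray())
print("S2 (protein x drug):")
print(net.S2.toarray())
print("S3 interaction score P1-P2:", net.S3.toarray()[0, 1])
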