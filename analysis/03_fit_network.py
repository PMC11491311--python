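"""Fit the Ising network by eLASSO and compare with the planted truth.

Nodewise L1 logistic regressions over a 100-point lambda grid, EBIC
selection at gamma = 0.25 and the AND rule.  Writes the network (JSON, edge
TSV, GraphML) and prints the recovered weights of the planted anchor edges
(ecstasy/other-drugs -> partners -> STD chain and the H8 quality-of-life
link) next to their true values.
"""

import sys
from pathlib import Path

from symptomnet.data_model import BinaryMatrix
from symptomnet.elasso import fit_ising
from symptomnet.ising import IsingNetwork

ANCHORS = (("XT", "PR"), ("OT", "PR"), ("PR", "ST"), ("H8", "QV"))


def main(out_root: str = "results") -> None:
    out = Path(out_root)
    matrix = BinaryMatrix.from_tsv(out / "binary_matrix.tsv")
    truth = IsingNetwork.from_json(out / "simulated" / "true_network.json")
    fit = fit_ising(matrix)  # defaults: gamma 0.25, AND rule
    net = fit.network
    net.to_json(out / "network.json")
    net.to_edgelist_tsv(out / "edges.tsv")
    net.to_graphml(out / "network.graphml")
    idx = {l: i for i, l in enumerate(net.node_labels)}
    print(f"fitted network: {net.n_edges} edges (truth has {truth.n_edges})")
    print("anchor edges (estimate / truth):")
    for a, b in ANCHORS:
        est = net.weights[idx[a], idx[b]]
        tru = truth.weights[idx[a], idx[b]]
        print(f"  {a}-{b}: {est:+.3f} / {tru:+.3f}")


if __name__ == "__main__":
    main(*sys.argv[1:])
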