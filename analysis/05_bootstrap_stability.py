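"""Bootstrap accuracy of edge weights and case-dropping stability.

Runs a scaled-down accuracy analysis on the simulated cohort: B = 50
row-resampling replicates for edge-weight CIs and difference tests, and a
case-dropping subset bootstrap (B = 25 per drop proportion over a coarse
grid) summarized by the CS coefficient.  The study-scale analysis uses
B = 1000; sizes here keep the driver to tens of minutes on one CPU while
the machinery is identical.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from symptomnet.bootstrap import (
    case_dropping,
    cs_coefficient,
    difference_test,
    edge_ci_bootstrap,
)
from symptomnet.data_model import BinaryMatrix

B_CI = 50
B_DROP = 25
SEED = 7
PROPORTIONS = (0.1, 0.25, 0.5, 0.75)


def main(out_root: str = "results") -> None:
    out = Path(out_root)
    matrix = BinaryMatrix.from_tsv(out / "binary_matrix.tsv")
    ci, ensemble = edge_ci_bootstrap(matrix, B=B_CI, seed=SEED)
    ci.to_csv(out / "edge_ci.tsv", sep="\t", index=False)
    sig_e, names_e = difference_test(ensemble, "edge")
    pd.DataFrame(sig_e.astype(int), index=names_e, columns=names_e).to_csv(
        out / "edge_difference.tsv", sep="\t"
    )
    sig_s, names_s = difference_test(ensemble, "strength")
    pd.DataFrame(sig_s.astype(int), index=names_s, columns=names_s).to_csv(
        out / "strength_difference.tsv", sep="\t"
    )
    stab = case_dropping(matrix, proportions=PROPORTIONS, B=B_DROP, seed=SEED)
    stab.to_frame().to_csv(out / "stability.tsv", sep="\t", index=False)
    cs = cs_coefficient(stab)
    (out / "stability.json").write_text(json.dumps({"cs_coefficient": cs}, indent=1))
    nonzero = ci[ci["estimate"] != 0]
    covered = (
        (nonzero["ci_lower"] <= nonzero["estimate"]) & (nonzero["estimate"] <= nonzero["ci_upper"])
    ).mean()
    print(f"edge CIs: {len(nonzero)} retained edges, replicate mean within CI for {covered:.0%}")
    print(f"significant edge-weight differences: {int(sig_e.sum() // 2)} pairs")
    print(f"significant strength differences: {int(sig_s.sum() // 2)} pairs")
    print(f"CS coefficient: {cs}")


if __name__ == "__main__":
    main(*sys.argv[1:])
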