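"""Strength centrality of the fitted network.

Strength = sum of absolute incident edge weights.  Writes the full table
and prints the five most central symptoms (in the cohort study this list
was led by impulsivity and depressive symptoms, with the "slowed down"
symptom H8 among the most central).
"""

import sys
from pathlib import Path

from symptomnet.centrality import strength
from symptomnet.ising import IsingNetwork


def main(out_root: str = "results") -> None:
    out = Path(out_root)
    net = IsingNetwork.from_json(out / "network.json")
    table = strength(net)
    table.to_csv(out / "centrality.tsv", sep="\t", index=False)
    print("top-5 strength centrality:")
    print(table.sort_values("rank").head(5).to_string(index=False))


if __name__ == "__main__":
    main(*sys.argv[1:])
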