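"""Impute and dichotomize the simulated cohort; report node prevalences.

Median-imputes the ordinal items, applies the per-instrument
dichotomization rules (reverse-keyed items reflected first, sex-specific
heavy-drinking threshold, VAS median split) and writes the 65-column binary
matrix plus the prevalence table under results/.
"""

import sys
from pathlib import Path

from symptomnet.data_model import (
    build_binary_matrix,
    impute_median,
    prevalence_report,
    read_response_table,
)


def main(out_root: str = "results") -> None:
    out = Path(out_root)
    table = read_response_table(out / "simulated" / "responses.csv")
    table = impute_median(table)
    matrix = build_binary_matrix(table)
    matrix.to_tsv(out / "binary_matrix.tsv")
    prev = prevalence_report(matrix)
    prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    top = prev.sort_values("percent", ascending=False).head(5)
    print(f"binary matrix: n={matrix.n}, p={matrix.p} -> {out / 'binary_matrix.tsv'}")
    print("highest-prevalence nodes:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main(*sys.argv[1:])
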