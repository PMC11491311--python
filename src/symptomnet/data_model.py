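"""Raw response ingestion: median imputation, dichotomization, binary matrix.

The raw input is one row per participant with ordinal questionnaire items
plus covariates (sex, weekly alcohol units, past-year partner count, past-year
STD flag, VAS).  This module turns that table into the n x 65 binary
symptom-presence matrix the Ising estimation runs on, and computes the
prevalence tables used for cohort description.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import (
    COVARIATE_COLUMNS,
    DEFAULT_INSTRUMENTS,
    EQ5D_DIMENSION_ITEMS,
    ITEM_RANGES,
    MATEQ_FREQ_ITEMS,
    NODE_LABELS,
    ORDINAL_ITEM_COLUMNS,
    InstrumentSpec,
)

__all__ = [
    "BinaryMatrix",
    "read_response_table",
    "impute_median",
    "dichotomize_item",
    "heavy_alcohol_flag",
    "build_binary_matrix",
    "prevalence_report",
    "percent_half_up",
]

#: symptom present iff (reflected) response >= cut, on the stated scale
RULES: dict[str, dict] = {
    # HADS 0-3: rate 0 stays 0, rates 1-3 become 1
    "hads": {"min": 0, "max": 3, "cut": 1},
    # BIS-11 1-4: rarely/never and sometimes -> 0; frequently, almost always -> 1
    "bis11": {"min": 1, "max": 4, "cut": 3},
    # MATE-Q 1b frequency (days used in past 30): any use -> 1
    "mateq_freq": {"min": 0, "max": 30, "cut": 1},
    # EQ-5D-5L 1-5: "no problems" -> 0, any problem level -> 1
    "eq5d": {"min": 1, "max": 5, "cut": 2},
    # MMAS-8 yes/no items are already binary
    "mmas_binary": {"min": 0, "max": 1, "cut": 1},
    # MMAS-8 T8 0-4: never -> 0; rarely .. daily -> 1
    "mmas_likert": {"min": 0, "max": 4, "cut": 1},
    # sexual-risk items arrive binary
    "sexrisk": {"min": 0, "max": 1, "cut": 1},
}

_MISSING_MARKERS = {"", "NA", "NaN", "nan", "N/A", None}


@dataclass(frozen=True)
class BinaryMatrix:
    """n participants x p binary nodes, with node labels in network order."""

    values: np.ndarray  # (n, p) int8 over {0, 1}
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape[1] != len(self.node_labels):
            raise ValueError("label count does not match column count")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1 with no missing values")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.node_labels))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(), tuple(df.columns))

    def select(self, labels: tuple[str, ...]) -> "BinaryMatrix":
        idx = [self.node_labels.index(l) for l in labels]
        return BinaryMatrix(self.values[:, idx], labels)


def read_response_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a raw response table (comma- or tab-delimited; autodetected).

    Empty fields and ``NA`` are treated as missing.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", "N/A"], keep_default_na=True)
    return df


def impute_median(
    table: pd.DataFrame, item_columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Median-impute missing ordinal responses, column by column.

    The per-item median of the observed values replaces every missing entry.
    When the median of an even-count column falls between two integer codes
    it is rounded down to the lower code (conservative toward "symptom
    absent").  Observed values are never changed.

    Raises
    ------
    ValueError
        If an item column is entirely missing, or an observed response lies
        outside the item's ordinal range.
    """
    out = table.copy()
    if item_columns is None:
        item_columns = tuple(c for c in ORDINAL_ITEM_COLUMNS if c in out.columns)
    for col in item_columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        observed = vals.dropna()
        if observed.empty:
            raise ValueError(f"item fully missing: {col}")
        lo, hi = ITEM_RANGES.get(col, (-np.inf, np.inf))
        bad = observed[(observed < lo) | (observed > hi)]
        if not bad.empty:
            raise ValueError(
                f"response out of range for item {col}: {sorted(bad.unique())} "
                f"(allowed {lo}..{hi})"
            )
        if vals.isna().any():
            med = int(np.floor(np.median(observed.to_numpy())))
            vals = vals.fillna(med)
        out[col] = vals.astype(int)
    return out


def dichotomize_item(rule_id: str, raw_value: float, reverse: bool = False) -> int:
    """Map one ordinal response to symptom present (1) / absent (0).

    Reverse-keyed items are reflected (``scale_min + scale_max - x``) before
    the instrument threshold is applied, so 1 always means "problem present".
    """
    try:
        rule = RULES[rule_id]
    except KeyError:
        raise ValueError(f"unknown dichotomization rule: {rule_id!r}") from None
    x = float(raw_value)
    if not (rule["min"] <= x <= rule["max"]):
        raise ValueError(
            f"raw value {raw_value} outside scale [{rule['min']}, {rule['max']}] "
            f"for rule {rule_id!r}"
        )
    if reverse:
        x = rule["min"] + rule["max"] - x
    return int(x >= rule["cut"])


def heavy_alcohol_flag(sex: str, units_per_week: float) -> int:
    """Heavy alcohol use: >21 weekly standard glasses in men, >14 in women."""
    if units_per_week < 0:
        raise ValueError("weekly alcohol units must be non-negative")
    s = str(sex).strip().lower()
    if s in {"male", "m"}:
        return int(units_per_week > 21)
    if s in {"female", "f"}:
        return int(units_per_week > 14)
    raise ValueError(f"unknown sex category: {sex!r}")


def _dichotomize_block(
    table: pd.DataFrame, spec: InstrumentSpec, codes: tuple[str, ...], rule_id: str
) -> np.ndarray:
    cols = []
    for code in codes:
        rule = "mmas_likert" if code == "T8" else rule_id
        raw = table[code].to_numpy()
        rev = spec.is_reverse(code)
        cols.append([dichotomize_item(rule, v, rev) for v in raw])
    return np.array(cols, dtype=np.int8).T


def build_binary_matrix(
    table: pd.DataFrame,
    instruments: tuple[InstrumentSpec, ...] = DEFAULT_INSTRUMENTS,
    multiple_partner_cut: int = 2,
    vas_split: str = "median",
) -> BinaryMatrix:
    """Dichotomize an imputed response table into the binary node matrix.

    Columns are ordered HADS, BIS-11, MATE-Q (AL, SM, CA, CO, XT, OT),
    EQ-5D-5L (QV, QP, QM, QS, QA), MMAS-8, sexual risk (PR, ST); p = 65 with
    all six instruments.  Derived nodes: AL from the sex-specific heavy-use
    threshold, QV = 1 iff VAS below the sample median, PR = 1 iff at least
    ``multiple_partner_cut`` partners in the past year, ST from the past-year
    STD flag.  Extra input columns (e.g. excluded MATE-Q substances) are
    ignored.
    """
    if table["participant_id"].duplicated().any():
        dupes = table.loc[table["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participant ids: {sorted(set(dupes))[:5]}")
    by_id = {s.instrument_id: s for s in instruments}
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for spec in instruments:
        iid = spec.instrument_id.value
        if iid in {"HADS", "BIS11"}:
            _require(table, spec.item_codes)
            blocks.append(_dichotomize_block(table, spec, spec.item_codes, spec.rule_id))
            labels.extend(spec.item_codes)
        elif iid == "MATEQ":
            _require(table, ("sex", "alcohol_units_week") + MATEQ_FREQ_ITEMS)
            al = np.array(
                [
                    heavy_alcohol_flag(s, u)
                    for s, u in zip(table["sex"], table["alcohol_units_week"])
                ],
                dtype=np.int8,
            )
            freq = _dichotomize_block(table, spec, MATEQ_FREQ_ITEMS, "mateq_freq")
            blocks.append(np.column_stack([al, freq]))
            labels.extend(("AL",) + MATEQ_FREQ_ITEMS)
        elif iid == "EQ5D5L":
            _require(table, ("vas",) + EQ5D_DIMENSION_ITEMS)
            vas = pd.to_numeric(table["vas"]).to_numpy(dtype=float)
            if np.isnan(vas).any():
                raise ValueError("vas column contains missing values")
            if vas_split != "median":
                raise ValueError(f"unknown vas_split: {vas_split!r}")
            qv = (vas < np.median(vas)).astype(np.int8)
            dims = _dichotomize_block(table, spec, EQ5D_DIMENSION_ITEMS, "eq5d")
            blocks.append(np.column_stack([qv, dims]))
            labels.extend(("QV",) + EQ5D_DIMENSION_ITEMS)
        elif iid == "MMAS8":
            _require(table, spec.item_codes)
            blocks.append(_dichotomize_block(table, spec, spec.item_codes, spec.rule_id))
            labels.extend(spec.item_codes)
        elif iid == "SEXRISK":
            _require(table, ("partners_year", "std_year"))
            partners = pd.to_numeric(table["partners_year"]).to_numpy()
            if (partners < 0).any():
                raise ValueError("partners_year must be non-negative")
            pr = (partners >= multiple_partner_cut).astype(np.int8)
            st = pd.to_numeric(table["std_year"]).to_numpy()
            if not np.isin(st, (0, 1)).all():
                raise ValueError("std_year must be 0/1")
            blocks.append(np.column_stack([pr, st.astype(np.int8)]))
            labels.extend(("PR", "ST"))
        else:  # pragma: no cover
            raise ValueError(f"unknown instrument: {iid}")
    return BinaryMatrix(np.column_stack(blocks), tuple(labels))


def _require(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing input columns: {missing}")


def percent_half_up(count: int, total_n: int) -> float:
    """Exact-rational percentage, rounded half-up to one decimal."""
    if total_n < 1:
        raise ValueError("total_n must be >= 1")
    if not (0 <= count <= total_n):
        raise ValueError("count must lie in [0, total_n]")
    tenths = Fraction(1000 * count, total_n) + Fraction(1, 2)
    return (tenths.numerator // tenths.denominator) / 10.0


def prevalence_report(
    matrix: BinaryMatrix | dict[str, int], total_n: int | None = None
) -> pd.DataFrame:
    """Per-node prevalence table: (label, count, n, percent).

    Accepts either a binary matrix or a mapping label -> count together with
    ``total_n`` (e.g. printed cohort counts).  Percentages use exact rational
    arithmetic before half-up rounding to one decimal.
    """
    if isinstance(matrix, BinaryMatrix):
        counts = {l: int(c) for l, c in zip(matrix.node_labels, matrix.values.sum(0))}
        total_n = matrix.n
    else:
        if total_n is None:
            raise ValueError("total_n is required with raw counts")
        counts = {str(k): int(v) for k, v in matrix.items()}
    rows = [
        (label, cnt, total_n, percent_half_up(cnt, total_n))
        for label, cnt in counts.items()
    ]
    return pd.DataFrame(rows, columns=["label", "count", "n", "percent"])
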