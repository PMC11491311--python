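"""Questionnaire instrument definitions for the 65-node symptom network.

Six instruments contribute nodes: HADS (anxiety/depression, 14 items),
BIS-11 (impulsivity, 30 items), MATE-Q part 1b (substance use, 6 retained
items), EQ-5D-5L (quality of life, 5 dimensions with the anxiety/depression
dimension dropped in favour of the HADS), MMAS-8 (ART adherence, 8 items)
and two sexual-risk items.  Reverse-keyed items are reflected onto the
symptom-present direction before thresholding, so that 1 uniformly means
"problem present".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Instrument(str, Enum):
    HADS = "HADS"
    BIS11 = "BIS11"
    MATEQ = "MATEQ"
    EQ5D5L = "EQ5D5L"
    MMAS8 = "MMAS8"
    SEXRISK = "SEXRISK"


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of one questionnaire block.

    Parameters
    ----------
    instrument_id
        Which instrument this block belongs to.
    item_codes
        Ordered node labels (e.g. ``H1``..``H14``).
    scale_min, scale_max
        Inclusive ordinal response range of the raw items.
    reverse_items
        Item codes that are reverse-keyed; they are reflected
        (``scale_min + scale_max - x``) before thresholding.
    rule_id
        Identifier of the dichotomization rule (see ``data_model.RULES``).
    """

    instrument_id: Instrument
    item_codes: tuple[str, ...]
    scale_min: int
    scale_max: int
    reverse_items: frozenset[str] = field(default_factory=frozenset)
    rule_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.item_codes)) != len(self.item_codes):
            raise ValueError("duplicate item codes within an instrument")
        unknown = self.reverse_items - set(self.item_codes)
        if unknown:
            raise ValueError(f"reverse flags for unknown items: {sorted(unknown)}")

    def is_reverse(self, code: str) -> bool:
        return code in self.reverse_items


HADS_ITEMS = tuple(f"H{i}" for i in range(1, 15))
HADS_REVERSE = frozenset({"H2", "H4", "H6", "H7", "H12", "H14"})

BIS_ITEMS = tuple(f"B{i}" for i in range(1, 31))
BIS_REVERSE = frozenset({"B1", "B7", "B8", "B10", "B12", "B13", "B15", "B29", "B30"})

# MATE-Q part 1b retained items.  Opioids, sedatives, gambling and "other
# stimulants" are excluded for negligible prevalence.  AL is derived from
# weekly alcohol units with a sex-specific heavy-use cut-off; the remaining
# items are past-30-day use frequencies.
MATEQ_ITEMS = ("AL", "SM", "CA", "CO", "XT", "OT")
MATEQ_FREQ_ITEMS = ("SM", "CA", "CO", "XT", "OT")

# EQ-5D-5L: QV is the (continuous) visual analogue scale; the other four are
# 5-level dimensions.  The anxiety/depression dimension is not a node.
EQ5D_ITEMS = ("QV", "QP", "QM", "QS", "QA")
EQ5D_DIMENSION_ITEMS = ("QP", "QM", "QS", "QA")

MMAS_ITEMS = tuple(f"T{i}" for i in range(1, 9))
MMAS_REVERSE = frozenset({"T5"})

SEXRISK_ITEMS = ("PR", "ST")

#: Final network column order: HADS, BIS-11, MATE-Q, EQ-5D-5L, MMAS-8, sexual risk.
NODE_LABELS: tuple[str, ...] = (
    HADS_ITEMS + BIS_ITEMS + MATEQ_ITEMS + EQ5D_ITEMS + MMAS_ITEMS + SEXRISK_ITEMS
)

HADS_SPEC = InstrumentSpec(Instrument.HADS, HADS_ITEMS, 0, 3, HADS_REVERSE, "hads")
BIS_SPEC = InstrumentSpec(Instrument.BIS11, BIS_ITEMS, 1, 4, BIS_REVERSE, "bis11")
MATEQ_SPEC = InstrumentSpec(Instrument.MATEQ, MATEQ_ITEMS, 0, 30, frozenset(), "mateq_freq")
EQ5D_SPEC = InstrumentSpec(Instrument.EQ5D5L, EQ5D_ITEMS, 1, 5, frozenset(), "eq5d")
MMAS_SPEC = InstrumentSpec(Instrument.MMAS8, MMAS_ITEMS, 0, 1, MMAS_REVERSE, "mmas_binary")
SEXRISK_SPEC = InstrumentSpec(Instrument.SEXRISK, SEXRISK_ITEMS, 0, 1, frozenset(), "sexrisk")

DEFAULT_INSTRUMENTS: tuple[InstrumentSpec, ...] = (
    HADS_SPEC,
    BIS_SPEC,
    MATEQ_SPEC,
    EQ5D_SPEC,
    MMAS_SPEC,
    SEXRISK_SPEC,
)

#: Ordinal questionnaire columns expected in a raw response table (the
#: remaining nodes are derived from covariate columns: AL from
#: sex/alcohol_units_week, QV from vas, PR from partners_year, ST from
#: std_year).  T8 is the single Likert MMAS-8 item (0-4).
ORDINAL_ITEM_COLUMNS: tuple[str, ...] = (
    HADS_ITEMS + BIS_ITEMS + MATEQ_FREQ_ITEMS + EQ5D_DIMENSION_ITEMS + MMAS_ITEMS
)

#: Inclusive raw ordinal range per item column.
ITEM_RANGES: dict[str, tuple[int, int]] = {}
ITEM_RANGES.update({c: (0, 3) for c in HADS_ITEMS})
ITEM_RANGES.update({c: (1, 4) for c in BIS_ITEMS})
ITEM_RANGES.update({c: (0, 30) for c in MATEQ_FREQ_ITEMS})
ITEM_RANGES.update({c: (1, 5) for c in EQ5D_DIMENSION_ITEMS})
ITEM_RANGES.update({c: (0, 1) for c in MMAS_ITEMS})
ITEM_RANGES["T8"] = (0, 4)

COVARIATE_COLUMNS = ("participant_id", "sex", "alcohol_units_week", "partners_year", "std_year", "vas")


def _check_unique_labels() -> None:
    if len(set(NODE_LABELS)) != len(NODE_LABELS):  # pragma: no cover
        raise AssertionError("node labels must be globally unique")


_check_unique_labels()
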