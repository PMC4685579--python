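"""Morphometric statistics: the RFamide basal index and cell-count ratios.

The basal index is the ratio of the RFamide-positive peduncle length to the
peduncle diameter, compared across groups with a two-sided Welch t-test
(unequal variances, Welch-Satterthwaite df) and a two-sided variance-ratio
F-test (doubling convention).  Units are arbitrary but must be consistent
within a dataset; the index itself is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError

CELL_CLASSES = ("icells", "nematoblasts", "nematocytes", "neurons", "gland_cells")


@dataclass(frozen=True)
class BasalIndexRecord:
    animal_id: str
    group: str
    rf_length: float
    diameter: float

    def __post_init__(self):
        if self.rf_length < 0:
            raise ValidationError(f"{self.animal_id}: rf_length must be >= 0")
        if not self.diameter > 0:
            raise ValidationError(f"{self.animal_id}: diameter must be > 0")


def basal_index(record: BasalIndexRecord) -> float:
    """rf_length / diameter; scale-invariant by construction."""
    return record.rf_length / record.diameter


def indices_table(records: Sequence[BasalIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "index": [basal_index(r) for r in records],
        }
    )


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    welch_t: float
    welch_df: float
    welch_p: float
    f_stat: float
    f_p: float


def compare_groups(
    records: Sequence[BasalIndexRecord], group_a: str, group_b: str
) -> GroupComparison:
    """Welch t and variance-ratio F between two groups of basal indices.

    The F statistic is reported as var(A)/var(B) so swapping the groups
    inverts it; its two-sided p uses the doubling convention and is
    therefore swap-invariant.  A group with zero variance makes the F-test
    undefined (NaN, flagged here by the NaN itself).
    """
    table = indices_table(records)
    a = table.loc[table["group"] == group_a, "index"].to_numpy(dtype=float)
    b = table.loc[table["group"] == group_b, "index"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 records")

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        t, df, p_t = 0.0, float(na + nb - 2), 1.0
    else:
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p_t = float(2 * stats.t.sf(abs(t), df))

    if va == 0 or vb == 0:
        f, p_f = np.nan, np.nan
    else:
        f = va / vb
        big = max(f, 1.0 / f)
        dfn, dfd = (na - 1, nb - 1) if f >= 1 else (nb - 1, na - 1)
        p_f = float(min(2 * stats.f.sf(big, dfn, dfd), 1.0))
    return GroupComparison(group_a, group_b, na, nb, float(t), float(df), p_t, float(f), p_f)


def compare_groups_report(
    records: Sequence[BasalIndexRecord], pairs: Sequence[tuple]
) -> pd.DataFrame:
    rows = []
    for ga, gb in pairs:
        c = compare_groups(records, ga, gb)
        rows.append(
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "welch_t": c.welch_t,
                "welch_df": c.welch_df,
                "welch_p": c.welch_p,
                "f_stat": c.f_stat,
                "f_p": c.f_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# maceration cell counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellCountRecord:
    sample_id: str
    condition: str
    icells: int
    nematoblasts: int
    nematocytes: int
    neurons: int
    gland_cells: int
    epithelial_cells: int

    def __post_init__(self):
        for name in CELL_CLASSES + ("epithelial_cells",):
            value = getattr(self, name)
            if value < 0 or int(value) != value:
                raise ValidationError(
                    f"{self.sample_id}: {name} count must be a non-negative integer"
                )
        if self.epithelial_cells <= 0:
            raise ValidationError(
                f"{self.sample_id}: epithelial count must be > 0 for ratio computation"
            )


def cell_class_ratios(record: CellCountRecord) -> dict:
    """Per-class ratio over epithelial cells and i-cell percentage of total."""
    total = record.epithelial_cells + sum(getattr(record, c) for c in CELL_CLASSES)
    if total <= 0:
        raise ValidationError(f"{record.sample_id}: zero total cell count")
    out = {
        f"{c}_over_epithelial": getattr(record, c) / record.epithelial_cells
        for c in CELL_CLASSES
    }
    out["icell_percent_of_total"] = 100.0 * record.icells / total
    out["total_counted"] = total
    return out


def cell_count_report(records: Sequence[CellCountRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "condition": r.condition}
        row.update(cell_class_ratios(r))
        rows.append(row)
    return pd.DataFrame(rows)


def read_basal_index_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"animal_id", "group", "rf_length", "diameter"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        BasalIndexRecord(str(r.animal_id), str(r.group), float(r.rf_length), float(r.diameter))
        for r in df.itertuples(index=False)
    ]


def read_cell_count_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "epithelial_cells"} | set(CELL_CLASSES)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CellCountRecord(
            str(r.sample_id),
            str(r.condition),
            int(r.icells),
            int(r.nematoblasts),
            int(r.nematocytes),
            int(r.neurons),
            int(r.gland_cells),
            int(r.epithelial_cells),
        )
        for r in df.itertuples(index=False)
    ]
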