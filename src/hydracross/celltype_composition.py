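"""Ternary cell-type composition from FACS-fraction transcriptomes.

Each gene receives an (ecto, endo, icell) share vector built from
geometric means of normalized counts per fraction, a categorical
cell-type-of-origin call, and optionally a contamination index comparing a
sorted fraction against unsorted body-column tissue.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix, RunConfig, SampleSheet, ValidationError
from .normalize_de import normalize, size_factors

FRACTIONS = ("ecto", "endo", "icell")


def _geometric_means(norm: pd.DataFrame, ids: Sequence[str], pseudo: float) -> np.ndarray:
    """exp(mean(log(y + pseudo))) - pseudo, clipped at 0.

    The pseudo-count keeps zero-containing genes finite inside the log and is
    subtracted back out so an all-zero gene maps to exactly 0.
    """
    vals = norm[list(ids)].to_numpy(dtype=float)
    g = np.exp(np.log(vals + pseudo).mean(axis=1)) - pseudo
    return np.maximum(g, 0.0)


def _fraction_ids(sheet: SampleSheet, condition: str) -> list:
    ids = [
        s.sample_id
        for s in sheet
        if s.experiment == "celltype" and s.condition == condition
    ]
    return ids


def ternary_compose(
    matrix: CountMatrix,
    sheet: SampleSheet,
    factors: Optional[Mapping[str, float]] = None,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Per-gene simplex shares over (ecto, endo, icell) plus a magnitude.

    Shares are geometric-mean normalized counts per fraction divided by their
    sum; the magnitude is that sum (it drives point sizes in ternary plots).
    Genes with zero sum are flagged undefined rather than dropped.
    """
    config = config or RunConfig()
    celltype_ids = [s.sample_id for s in sheet if s.experiment == "celltype"]
    if not celltype_ids:
        raise ValidationError("no celltype samples in sheet")
    for fraction in FRACTIONS:
        if len(_fraction_ids(sheet, fraction)) < 2:
            raise ValidationError(f"fraction {fraction!r}: >= 2 replicates required")
    sub = matrix.subset_samples(celltype_ids)
    if factors is None:
        factors = size_factors(sub, fallback=True)
    norm = normalize(sub, factors)

    geo = {
        fraction: _geometric_means(norm, _fraction_ids(sheet, fraction), config.pseudo_count)
        for fraction in FRACTIONS
    }
    total = sum(geo.values())
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = {f: np.where(defined, geo[f] / total, np.nan) for f in FRACTIONS}
    return pd.DataFrame(
        {
            "gene_id": list(matrix.gene_ids),
            "f_ecto": shares["ecto"],
            "f_endo": shares["endo"],
            "f_icell": shares["icell"],
            "magnitude": total,
            "defined": defined,
        }
    )


def call_celltype(composition: pd.DataFrame, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Categorical label per gene from its simplex shares.

    A single fraction wins outright at share >= ``specific_fraction``;
    ``both_epithelial`` requires a low i-cell share and balanced epithelial
    shares; everything else is ``mixed``.  Undefined compositions get an
    ``undefined`` label.
    """
    config = config or RunConfig()
    labels = []
    for row in composition.itertuples(index=False):
        if not row.defined or np.isnan(row.f_ecto):
            labels.append("undefined")
            continue
        shares = {"ecto": row.f_ecto, "endo": row.f_endo, "icell": row.f_icell}
        winner = max(shares, key=shares.get)
        if shares[winner] >= config.specific_fraction:
            labels.append(winner)
        elif (
            row.f_icell <= config.shared_floor
            and abs(row.f_ecto - row.f_endo) <= config.epithelial_balance
        ):
            labels.append("both_epithelial")
        else:
            labels.append("mixed")
    out = composition[["gene_id"]].copy()
    out["celltype_label"] = labels
    return out


def contamination_index(
    matrix: CountMatrix,
    sheet: SampleSheet,
    factors: Optional[Mapping[str, float]] = None,
    fraction: str = "endo",
    config: Optional[RunConfig] = None,
) -> pd.Series:
    """Per-gene (fraction geometric mean) / (unsorted geometric mean).

    Genes absent from the fraction give 0; genes with zero unsorted level are
    undefined (NaN).  The per-gene-set summary of interest is the median over
    an annotated set, e.g. gland genes.
    """
    config = config or RunConfig()
    if fraction not in FRACTIONS:
        raise ValidationError(f"unknown fraction {fraction!r}")
    unsorted_ids = _fraction_ids(sheet, "unsorted")
    if not unsorted_ids:
        raise ValidationError("no unsorted samples present")
    fraction_ids = _fraction_ids(sheet, fraction)
    celltype_ids = [s.sample_id for s in sheet if s.experiment == "celltype"]
    sub = matrix.subset_samples(celltype_ids)
    if factors is None:
        factors = size_factors(sub, fallback=True)
    norm = normalize(sub, factors)
    level_fraction = _geometric_means(norm, fraction_ids, config.pseudo_count)
    level_unsorted = _geometric_means(norm, unsorted_ids, config.pseudo_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(level_unsorted > 0, level_fraction / level_unsorted, np.nan)
    return pd.Series(ratio, index=list(matrix.gene_ids), name=f"{fraction}_over_unsorted")


def summarize_contamination(index: pd.Series, gene_set: Sequence[str]) -> float:
    """Median contamination ratio over a gene set (NaN entries excluded)."""
    vals = index.reindex(list(gene_set)).dropna()
    if vals.empty:
        raise ValidationError("gene set has no defined contamination ratios")
    return float(vals.median())
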