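"""Treatment-response signature calling and the final cross-classification.

Joins the three ablation contexts (HU, HS, Col) per gene, applies the
precedence cascade icell_lost > gland_signature > plasticity_candidate >
down_other > up_other > unresponsive, partitions up/down gene sets into
Venn cells, and assembles the final candidate table by crossing signatures
with cell-type and spatial-pattern calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneAnnotation, RunConfig, ValidationError

CONTEXTS = ("HU", "HS", "Col")
SIGNATURE_LABELS = (
    "icell_lost",
    "gland_signature",
    "plasticity_candidate",
    "down_other",
    "up_other",
    "unresponsive",
)


@dataclass(frozen=True)
class VennPartition:
    direction: str
    cells: Dict[str, int]   # keys: HU, HS, Col, HU&HS, HU&Col, HS&Col, HU&HS&Col
    totals: Dict[str, int]  # per-context totals

    def __post_init__(self):
        covering = {
            "HU": ("HU", "HU&HS", "HU&Col", "HU&HS&Col"),
            "HS": ("HS", "HU&HS", "HS&Col", "HU&HS&Col"),
            "Col": ("Col", "HU&Col", "HS&Col", "HU&HS&Col"),
        }
        for ctx, keys in covering.items():
            if self.totals[ctx] != sum(self.cells[k] for k in keys):
                raise ValidationError(
                    f"Venn inclusion-exclusion failed for context {ctx}"
                )
        if any(v < 0 for v in self.cells.values()):
            raise ValidationError("negative Venn cell count")


def context_responses(
    de_results: Mapping[str, pd.DataFrame],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Wide per-gene join of the three terminal DE contrasts.

    Columns per context: fold_<ctx>, fdr_<ctx>, plus the derived membership
    columns up_<ctx> (fold >= up_fold and fdr <= fdr_alpha) and
    down90_<ctx> (retention <= down_retention).  Genes missing from a
    context carry NaN fold and are counted in no set.
    """
    config = config or RunConfig()
    missing = [c for c in CONTEXTS if c not in de_results]
    if missing:
        raise ValidationError(f"missing DE results for context(s): {missing}")
    frames = []
    for ctx in CONTEXTS:
        de = de_results[ctx]
        frame = de[["gene_id"]].copy()
        fold = 2.0 ** de["log2fc"].to_numpy()
        frame[f"fold_{ctx}"] = fold
        frame[f"fdr_{ctx}"] = de["fdr"].to_numpy()
        frames.append(frame)
    out = frames[0]
    for frame in frames[1:]:
        out = out.merge(frame, on="gene_id", how="outer")
    for ctx in CONTEXTS:
        fold = out[f"fold_{ctx}"]
        fdr = out[f"fdr_{ctx}"]
        out[f"up_{ctx}"] = (fold >= config.up_fold) & (fdr <= config.fdr_alpha)
        out[f"down90_{ctx}"] = fold <= config.down_retention
        out[f"up_{ctx}"] = out[f"up_{ctx}"].fillna(False)
        out[f"down90_{ctx}"] = out[f"down90_{ctx}"].fillna(False)
    return out


def call_signatures(
    responses: pd.DataFrame, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """One mutually-exclusive signature label per gene.

    Precedence: (1) icell_lost -- retention <= down_retention in all three
    contexts; (2) gland_signature -- retention <= down_retention in Col and
    fold >= stable_floor in both HU and HS; (3) plasticity_candidate --
    >= min_contexts contexts up; (4) down_other; (5) up_other;
    (6) unresponsive.
    """
    config = config or RunConfig()
    labels = []
    for row in responses.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(responses.columns, row))
        down = {c: bool(d[f"down90_{c}"]) for c in CONTEXTS}
        up = {c: bool(d[f"up_{c}"]) for c in CONTEXTS}
        folds = {c: d[f"fold_{c}"] for c in CONTEXTS}
        if all(down.values()):
            labels.append("icell_lost")
        elif (
            down["Col"]
            and not np.isnan(folds["HU"]) and folds["HU"] >= config.stable_floor
            and not np.isnan(folds["HS"]) and folds["HS"] >= config.stable_floor
        ):
            labels.append("gland_signature")
        elif sum(up.values()) >= config.min_contexts:
            labels.append("plasticity_candidate")
        elif any(down.values()):
            labels.append("down_other")
        elif sum(up.values()) == 1:
            labels.append("up_other")
        else:
            labels.append("unresponsive")
    out = responses.copy()
    out["label"] = labels
    out["contexts_up"] = [
        ",".join(c for c in CONTEXTS if row[f"up_{c}"]) for _, row in responses.iterrows()
    ]
    out["contexts_down90"] = [
        ",".join(c for c in CONTEXTS if row[f"down90_{c}"]) for _, row in responses.iterrows()
    ]
    return out


def venn_partition(
    responses: pd.DataFrame,
    direction: str,
    config: Optional[RunConfig] = None,
) -> VennPartition:
    """Disjoint seven-cell partition of context membership sets."""
    config = config or RunConfig()
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    prefix = "up" if direction == "up" else "down90"
    member = {c: responses[f"{prefix}_{c}"].fillna(False).to_numpy(dtype=bool) for c in CONTEXTS}
    hu, hs, col = member["HU"], member["HS"], member["Col"]
    cells = {
        "HU": int((hu & ~hs & ~col).sum()),
        "HS": int((~hu & hs & ~col).sum()),
        "Col": int((~hu & ~hs & col).sum()),
        "HU&HS": int((hu & hs & ~col).sum()),
        "HU&Col": int((hu & ~hs & col).sum()),
        "HS&Col": int((~hu & hs & col).sum()),
        "HU&HS&Col": int((hu & hs & col).sum()),
    }
    totals = {c: int(member[c].sum()) for c in CONTEXTS}
    return VennPartition(direction, cells, totals)


def cross_classify(
    signature_calls: pd.DataFrame,
    celltype_calls: pd.DataFrame,
    pattern_calls: Optional[pd.DataFrame] = None,
    annotation: Optional[Mapping[str, GeneAnnotation]] = None,
):
    """Final candidate table: plasticity candidates attributed to epithelia.

    Returns (candidates, gland_table, diagnostics).  Candidates are
    plasticity_candidate genes whose cell-type call is ecto / endo /
    both_epithelial, sorted by maximal fold (descending) with a gene_id
    tie-break; plasticity candidates with other cell-type calls go to the
    diagnostics sheet.  Gland-signature genes are reported separately.
    Genes missing from the cell-type table are dropped from the join, with
    the count recorded in diagnostics.
    """
    sig = signature_calls
    fold_cols = [f"fold_{c}" for c in CONTEXTS]
    merged = sig.merge(celltype_calls[["gene_id", "celltype_label"]], on="gene_id", how="left")
    unmatched = merged["celltype_label"].isna()
    n_unmatched = int(unmatched.sum())
    merged = merged[~unmatched].copy()
    if pattern_calls is not None:
        merged = merged.merge(
            pattern_calls[["gene_id", "pattern"]], on="gene_id", how="left"
        )
    else:
        merged["pattern"] = np.nan
    if annotation:
        merged["category"] = [
            annotation[g].category if g in annotation else "other" for g in merged["gene_id"]
        ]
        merged["family_label"] = [
            (annotation[g].family_label or "") if g in annotation else ""
            for g in merged["gene_id"]
        ]
    else:
        merged["category"] = "other"
        merged["family_label"] = ""
    merged["max_fold"] = merged[fold_cols].max(axis=1)

    is_candidate = merged["label"] == "plasticity_candidate"
    epithelial = merged["celltype_label"].isin(("ecto", "endo", "both_epithelial"))
    candidates = merged[is_candidate & epithelial].copy()
    non_epithelial = merged[is_candidate & ~epithelial].copy()
    gland = merged[merged["label"] == "gland_signature"].copy()

    sort_kw = dict(ascending=[False, True], kind="mergesort")
    candidates = candidates.sort_values(["max_fold", "gene_id"], **sort_kw).reset_index(drop=True)
    gland = gland.sort_values(["max_fold", "gene_id"], **sort_kw).reset_index(drop=True)
    diagnostics = {
        "n_unmatched_celltype": n_unmatched,
        "non_epithelial_candidates": non_epithelial.reset_index(drop=True),
    }
    keep = [
        "gene_id", "label", "celltype_label", "pattern", "category", "family_label",
        "contexts_up", "contexts_down90", "max_fold",
    ] + fold_cols + [f"fdr_{c}" for c in CONTEXTS]
    keep = [c for c in keep if c in candidates.columns]
    return candidates[keep], gland[keep], diagnostics


def kinetics_profile(
    fold_table: pd.DataFrame,
    gene_set: Sequence[str],
    context: str = "HU",
    tol: float = 0.25,
) -> pd.DataFrame:
    """Per-gene log2-fold time course in one context, day 0 forced to 0.

    Timepoints absent from the fold table stay absent (no interpolation).
    The monotone flag is non-decreasing within ``tol`` log2 units.
    """
    sub = fold_table[fold_table["context"] == context]
    if sub.empty:
        raise ValidationError(f"no fold-table rows for context {context!r}")
    wide = sub.pivot(index="gene_id", columns="timepoint_days", values="log2fc")
    wide = wide.reindex([g for g in gene_set if g in wide.index])
    if 0.0 in wide.columns:
        wide[0.0] = 0.0  # time-0 convention
    days = sorted(wide.columns)
    profile = wide[days]
    diffs = profile.to_numpy()[:, 1:] - profile.to_numpy()[:, :-1]
    monotone = np.all(np.isnan(diffs) | (diffs >= -tol), axis=1)
    out = profile.reset_index()
    out.columns = ["gene_id"] + [f"log2fc_d{d:g}" for d in days]
    out["monotone"] = monotone
    return out
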