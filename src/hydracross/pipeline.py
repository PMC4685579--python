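"""End-to-end orchestration over the three synthetic designs.

Used by the ``run-all`` CLI subcommand, the acceptance tests and the
acceptance report: simulate all designs, run every analysis stage, and
score parameter recovery against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import celltype_composition as ct
from . import normalize_de as nd
from . import signatures as sg
from . import spatial_patterns as sp
from . import synthetic_data as sd
from .io_core import RunConfig


@dataclass
class PipelineResult:
    config: RunConfig
    design: sd.SimulationDesign
    spatial_calls: pd.DataFrame
    spatial_truth: pd.DataFrame
    spatial_metrics: pd.DataFrame
    spatial_accuracy: float
    de_results: Dict[str, pd.DataFrame]
    fold_table: pd.DataFrame
    responses: pd.DataFrame
    signature_calls: pd.DataFrame
    venn_up: sg.VennPartition
    venn_down: sg.VennPartition
    composition: pd.DataFrame
    celltype_calls: pd.DataFrame
    contamination: pd.Series
    candidates: pd.DataFrame
    gland_table: pd.DataFrame
    diagnostics: dict
    treatment_truth: pd.DataFrame
    celltype_truth: pd.DataFrame
    recovery: dict = field(default_factory=dict)


def run_synthetic_pipeline(
    seed: int = 0,
    config: Optional[RunConfig] = None,
    design: Optional[sd.SimulationDesign] = None,
    programs=None,
) -> PipelineResult:
    """Simulate all three designs at one seed and run every stage."""
    config = config or RunConfig(rng_seed=seed)
    design = design or sd.SimulationDesign(rng_seed=seed)
    if programs is None:
        programs = sd.default_programs(rng_seed=seed)

    # --- spatial ---------------------------------------------------------
    sp_cm, sp_sheet, sp_truth = sd.simulate_spatial(design, programs)
    profiles = sp.build_profiles(sp_cm, sp_sheet, config=config)
    spatial_calls = sp.classify_all(profiles, config)
    detected = spatial_calls["pattern"] != "undetected"
    confusion, metrics, accuracy = sp.score_spatial_recovery(
        spatial_calls[detected], sp_truth
    )

    # --- treatment -------------------------------------------------------
    tr_cm, tr_sheet, tr_truth = sd.simulate_treatment(design, programs)
    contrasts = nd.terminal_contrasts(tr_sheet, design.day_match)
    de_results = {
        ctx: nd.nb_wald_test(
            tr_cm,
            tr_sheet,
            (c_ids, t_ids),
            dispersion_mode=config.dispersion_mode,
            fallback=True,
            fold_pseudo=config.fold_pseudo,
        )
        for ctx, (c_ids, t_ids) in contrasts.items()
    }
    fold_table = nd.fold_change_table(tr_cm, tr_sheet, config, design.day_match)
    responses = sg.context_responses(de_results, config)
    signature_calls = sg.call_signatures(responses, config)
    venn_up = sg.venn_partition(responses, "up", config)
    venn_down = sg.venn_partition(responses, "down", config)

    # --- celltype --------------------------------------------------------
    ct_cm, ct_sheet, ct_truth = sd.simulate_celltype(design, programs)
    composition = ct.ternary_compose(ct_cm, ct_sheet, config=config)
    celltype_calls = ct.call_celltype(composition, config)
    contamination = ct.contamination_index(ct_cm, ct_sheet, fraction="endo", config=config)

    # --- cross-classification -------------------------------------------
    candidates, gland_table, diagnostics = sg.cross_classify(
        signature_calls, celltype_calls, spatial_calls
    )

    truth = sd.truth_table(programs)
    recovery = score_recovery(truth, signature_calls, candidates, gland_table, design, contamination)

    return PipelineResult(
        config=config,
        design=design,
        spatial_calls=spatial_calls,
        spatial_truth=sp_truth,
        spatial_metrics=metrics,
        spatial_accuracy=accuracy,
        de_results=de_results,
        fold_table=fold_table,
        responses=responses,
        signature_calls=signature_calls,
        venn_up=venn_up,
        venn_down=venn_down,
        composition=composition,
        celltype_calls=celltype_calls,
        contamination=contamination,
        candidates=candidates,
        gland_table=gland_table,
        diagnostics=diagnostics,
        treatment_truth=tr_truth,
        celltype_truth=ct_truth,
        recovery=recovery,
    )


def _sens_prec(true_set: set, called_set: set):
    tp = len(true_set & called_set)
    sens = tp / len(true_set) if true_set else np.nan
    prec = tp / len(called_set) if called_set else np.nan
    return sens, prec


def score_recovery(
    truth: pd.DataFrame,
    signature_calls: pd.DataFrame,
    candidates: pd.DataFrame,
    gland_table: pd.DataFrame,
    design: sd.SimulationDesign,
    contamination: Optional[pd.Series] = None,
) -> dict:
    """Sensitivity/precision of the final tables against planted truth."""
    epithelial = {"ecto", "endo", "both_epithelial"}
    true_plasticity = set(
        truth.loc[
            (truth["treatment_class"] == "plasticity_up")
            & truth["true_celltype"].isin(epithelial),
            "gene_id",
        ]
    )
    true_gland = set(truth.loc[truth["treatment_class"] == "gland_signature", "gene_id"])
    called_plasticity = set(candidates["gene_id"])
    called_gland = set(gland_table["gene_id"])
    p_sens, p_prec = _sens_prec(true_plasticity, called_plasticity)
    g_sens, g_prec = _sens_prec(true_gland, called_gland)
    out = {
        "n_true_plasticity": len(true_plasticity),
        "n_called_plasticity": len(called_plasticity),
        "plasticity_sensitivity": p_sens,
        "plasticity_precision": p_prec,
        "n_true_gland": len(true_gland),
        "n_called_gland": len(called_gland),
        "gland_sensitivity": g_sens,
        "gland_precision": g_prec,
    }
    if contamination is not None and true_gland:
        from .celltype_composition import summarize_contamination

        out["gland_contamination_estimate"] = summarize_contamination(
            contamination, sorted(true_gland)
        )
        out["gland_contamination_truth"] = design.contamination.get("endo", (None, np.nan))[1]
    return out
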