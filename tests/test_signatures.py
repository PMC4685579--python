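import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydracross.io_core import RunConfig, ValidationError
from hydracross import signatures as sg

CONTEXTS = sg.CONTEXTS


def de_frame(genes, folds, fdrs):
    folds = np.asarray(folds, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": 100.0,
            "log2fc": np.log2(folds),
            "se_log2fc": 0.1,
            "p_value": fdrs,
            "fdr": fdrs,
            "status": "ok",
        }
    )


def responses_for(folds_by_ctx, fdrs_by_ctx, genes=("g1",), config=None):
    de = {
        ctx: de_frame(list(genes), folds_by_ctx[ctx], fdrs_by_ctx[ctx]) for ctx in CONTEXTS
    }
    return sg.context_responses(de, config or RunConfig())


class TestContextResponses:
    def test_two_contexts_up(self):
        r = responses_for(
            {"HU": [4], "HS": [3], "Col": [0.5]},
            {"HU": [0.01], "HS": [0.02], "Col": [0.01]},
        )
        row = r.iloc[0]
        assert row.up_HU and row.up_HS and not row.up_Col

    def test_fdr_excludes_context(self):
        r = responses_for(
            {"HU": [4], "HS": [1], "Col": [1]},
            {"HU": [0.5], "HS": [0.5], "Col": [0.5]},
        )
        assert not r.iloc[0].up_HU

    def test_flat_gene_no_memberships(self):
        r = responses_for(
            {"HU": [1], "HS": [1], "Col": [1]},
            {"HU": [0.9], "HS": [0.9], "Col": [0.9]},
        )
        row = r.iloc[0]
        assert not (row.up_HU or row.up_HS or row.up_Col)
        assert not (row.down90_HU or row.down90_HS or row.down90_Col)

    def test_missing_context_raises(self):
        de = {"HU": de_frame(["g"], [1], [0.5])}
        with pytest.raises(ValidationError):
            sg.context_responses(de, RunConfig())

    def test_gene_missing_from_one_context(self):
        de = {
            "HU": de_frame(["g1", "g2"], [4, 1], [0.01, 0.5]),
            "HS": de_frame(["g1"], [4], [0.01]),
            "Col": de_frame(["g1", "g2"], [1, 1], [0.5, 0.5]),
        }
        r = sg.context_responses(de, RunConfig())
        g2 = r[r.gene_id == "g2"].iloc[0]
        assert np.isnan(g2.fold_HS)
        assert not g2.up_HS


class TestCallSignatures:
    def _label(self, folds, fdrs, config=None):
        r = responses_for(
            {c: [folds[i]] for i, c in enumerate(CONTEXTS)},
            {c: [fdrs[i]] for i, c in enumerate(CONTEXTS)},
            config=config,
        )
        return sg.call_signatures(r, config or RunConfig()).iloc[0].label

    def test_icell_lost(self):
        assert self._label([0.05, 0.04, 0.06], [0.01, 0.01, 0.01]) == "icell_lost"

    def test_gland_signature(self):
        assert self._label([1.1, 1.3, 0.05], [0.5, 0.5, 0.01]) == "gland_signature"

    def test_plasticity_two_contexts(self):
        assert self._label([4.1, 2.5, 1.2], [0.01, 0.05, 0.9]) == "plasticity_candidate"

    def test_down_other(self):
        assert self._label([0.05, 1.0, 1.0], [0.01, 0.9, 0.9]) == "down_other"

    def test_up_other(self):
        assert self._label([4.0, 1.0, 1.0], [0.01, 0.9, 0.9]) == "up_other"

    def test_unresponsive(self):
        assert self._label([1.0, 1.0, 1.0], [0.9, 0.9, 0.9]) == "unresponsive"

    def test_labels_partition(self, pipeline_result):
        calls = pipeline_result.signature_calls
        assert calls.label.isin(sg.SIGNATURE_LABELS).all()
        assert calls.gene_id.is_unique

    def test_up_fold_monotonicity(self):
        """Raising up_fold can only shrink contexts_up."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(100)]
        folds = {c: rng.uniform(0.2, 6.0, 100) for c in CONTEXTS}
        fdrs = {c: rng.uniform(0, 0.3, 100) for c in CONTEXTS}
        sizes = []
        for up_fold in (1.5, 2.0, 3.0, 4.5):
            cfg = RunConfig(up_fold=up_fold)
            r = responses_for(folds, fdrs, genes=genes, config=cfg)
            sizes.append(
                sum(r[f"up_{c}"].sum() for c in CONTEXTS)
            )
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestVennPartition:
    def _responses(self, membership):
        """membership: dict gene -> set of contexts (up)."""
        genes = sorted(membership)
        folds = {c: [4.0 if c in membership[g] else 1.0 for g in genes] for c in CONTEXTS}
        fdrs = {c: [0.01] * len(genes) for c in CONTEXTS}
        return responses_for(folds, fdrs, genes=genes)

    def test_disjoint_singletons(self):
        membership = {}
        for i in range(2):
            membership[f"a{i}"] = {"HU"}
        for i in range(3):
            membership[f"b{i}"] = {"HS"}
        for i in range(4):
            membership[f"c{i}"] = {"Col"}
        venn = sg.venn_partition(self._responses(membership), "up")
        assert venn.cells == {
            "HU": 2, "HS": 3, "Col": 4,
            "HU&HS": 0, "HU&Col": 0, "HS&Col": 0, "HU&HS&Col": 0,
        }

    def test_all_triple(self):
        membership = {f"g{i}": {"HU", "HS", "Col"} for i in range(5)}
        venn = sg.venn_partition(self._responses(membership), "up")
        assert venn.cells["HU&HS&Col"] == 5
        assert sum(v for k, v in venn.cells.items() if k != "HU&HS&Col") == 0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sets(st.sampled_from(CONTEXTS)), min_size=0, max_size=60))
    def test_matches_set_algebra(self, memberships):
        membership = {f"g{i:03d}": m for i, m in enumerate(memberships)}
        venn = sg.venn_partition(self._responses(membership), "up") if membership else None
        if venn is None:
            return
        # independent brute-force set algebra
        sets = {c: {g for g, m in membership.items() if c in m} for c in CONTEXTS}
        hu, hs, col = sets["HU"], sets["HS"], sets["Col"]
        expected = {
            "HU": len(hu - hs - col),
            "HS": len(hs - hu - col),
            "Col": len(col - hu - hs),
            "HU&HS": len((hu & hs) - col),
            "HU&Col": len((hu & col) - hs),
            "HS&Col": len((hs & col) - hu),
            "HU&HS&Col": len(hu & hs & col),
        }
        assert venn.cells == expected
        assert venn.totals == {c: len(sets[c]) for c in CONTEXTS}

    def test_inclusion_exclusion_enforced(self):
        with pytest.raises(ValidationError):
            sg.VennPartition(
                "up",
                {"HU": 1, "HS": 0, "Col": 0, "HU&HS": 0, "HU&Col": 0, "HS&Col": 0,
                 "HU&HS&Col": 0},
                {"HU": 2, "HS": 0, "Col": 0},
            )

    def test_pipeline_venn_consistent(self, pipeline_result):
        for venn in (pipeline_result.venn_up, pipeline_result.venn_down):
            assert sum(venn.cells.values()) >= max(venn.totals.values())


class TestCrossClassify:
    def test_non_epithelial_candidate_diverted(self):
        sig = responses_for(
            {"HU": [4, 4], "HS": [4, 4], "Col": [1, 1]},
            {"HU": [0.01, 0.01], "HS": [0.01, 0.01], "Col": [0.9, 0.9]},
            genes=("e1", "i1"),
        )
        calls = sg.call_signatures(sig, RunConfig())
        celltype = pd.DataFrame(
            {"gene_id": ["e1", "i1"], "celltype_label": ["ecto", "icell"]}
        )
        candidates, gland, diag = sg.cross_classify(calls, celltype)
        assert list(candidates.gene_id) == ["e1"]
        assert list(diag["non_epithelial_candidates"].gene_id) == ["i1"]

    def test_empty_candidates(self):
        sig = responses_for(
            {"HU": [1], "HS": [1], "Col": [1]},
            {"HU": [0.9], "HS": [0.9], "Col": [0.9]},
        )
        calls = sg.call_signatures(sig, RunConfig())
        celltype = pd.DataFrame({"gene_id": ["g1"], "celltype_label": ["ecto"]})
        candidates, gland, _ = sg.cross_classify(calls, celltype)
        assert candidates.empty and gland.empty

    def test_unmatched_gene_counted(self):
        sig = responses_for(
            {"HU": [4], "HS": [4], "Col": [1]},
            {"HU": [0.01], "HS": [0.01], "Col": [0.9]},
        )
        calls = sg.call_signatures(sig, RunConfig())
        celltype = pd.DataFrame({"gene_id": ["other"], "celltype_label": ["ecto"]})
        _, _, diag = sg.cross_classify(calls, celltype)
        assert diag["n_unmatched_celltype"] == 1

    def test_sorted_by_max_fold(self, pipeline_result):
        cand = pipeline_result.candidates
        assert (cand.max_fold.diff().dropna() <= 1e-12).all()

    def test_end_to_end_recovery(self, pipeline_result):
        """25 planted epithelial plasticity genes and 9 gland-signature genes
        recovered at >= 23/25 and >= 8/9."""
        rec = pipeline_result.recovery
        assert rec["n_true_plasticity"] == 25
        assert rec["n_true_gland"] == 9
        assert rec["plasticity_sensitivity"] * rec["n_true_plasticity"] >= 23
        assert rec["gland_sensitivity"] * rec["n_true_gland"] >= 8


class TestKineticsProfile:
    def test_monotone_flag_noise_free(self):
        from hydracross import normalize_de as nd
        from hydracross import synthetic_data as sd

        design = sd.SimulationDesign(rng_seed=0, nb_dispersion=0.0, library_size_log_sd=0.0)
        programs = sd.default_programs(rng_seed=0)
        cm, sheet, truth = sd.simulate_treatment(design, programs)
        table = nd.fold_change_table(cm, sheet, RunConfig(), design.day_match)
        plast = truth[truth.treatment_class == "plasticity_up"].gene_id
        prof = sg.kinetics_profile(table, list(plast))
        assert prof.monotone.all()

    def test_day0_forced_zero(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g"] * 2,
                "context": ["HU"] * 2,
                "timepoint_days": [0.0, 7.0],
                "log2fc": [1.5, 2.0],
                "fold": [2.8, 4.0],
            }
        )
        prof = sg.kinetics_profile(table, ["g"])
        assert prof.iloc[0]["log2fc_d0"] == 0.0

    def test_unresponsive_near_zero(self, pipeline_result):
        truth = pipeline_result.treatment_truth
        flat = truth[truth.treatment_class == "unresponsive"].gene_id[:50]
        prof = sg.kinetics_profile(pipeline_result.fold_table, list(flat))
        vals = prof[[c for c in prof.columns if c.startswith("log2fc")]].to_numpy()
        assert np.nanmean(np.abs(vals)) < 0.3

    def test_missing_context_raises(self):
        table = pd.DataFrame(
            {"gene_id": ["g"], "context": ["HS"], "timepoint_days": [7.0],
             "log2fc": [1.0], "fold": [2.0]}
        )
        with pytest.raises(ValidationError):
            sg.kinetics_profile(table, ["g"], context="HU")
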