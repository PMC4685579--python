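import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hydracross.io_core import CountMatrix, RunConfig, ValidationError
from hydracross import normalize_de as nd
from hydracross import synthetic_data as sd


def brute_force_size_factors(counts):
    """Independent one-line-per-step evaluation of median-of-ratios."""
    counts = np.asarray(counts, dtype=float)
    ref_rows = [i for i in range(counts.shape[0]) if all(c > 0 for c in counts[i])]
    geo = {i: np.prod(counts[i]) ** (1.0 / counts.shape[1]) for i in ref_rows}
    factors = []
    for j in range(counts.shape[1]):
        ratios = sorted(counts[i, j] / geo[i] for i in ref_rows)
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def _matrix(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        tuple(f"g{i}" for i in range(counts.shape[0])),
        tuple(f"s{j}" for j in range(counts.shape[1])),
        counts,
    )


class TestSizeFactors:
    def test_exact_scaling(self):
        a = np.array([[10], [20], [5], [100]])
        cm = _matrix(np.hstack([a, 2 * a]))
        f = nd.size_factors(cm)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        cm = _matrix(np.tile([[10], [20], [5]], (1, 4)))
        f = nd.size_factors(cm)
        assert np.allclose(f, f.iloc[0])

    def test_matches_brute_force_random(self, small_random_matrix):
        f = nd.size_factors(small_random_matrix, fallback=False)
        expected = brute_force_size_factors(small_random_matrix.counts)
        assert np.allclose(f.to_numpy(), expected, rtol=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(arrays(np.int64, (12, 5), elements=st.integers(0, 500)))
    def test_property_matches_brute_force(self, counts):
        counts[0] = np.maximum(counts[0], 1)  # keep the reference set non-empty
        counts[1] = np.maximum(counts[1], 3)
        cm = _matrix(counts)
        f = nd.size_factors(cm)
        assert np.allclose(f.to_numpy(), brute_force_size_factors(counts), rtol=1e-10)

    def test_empty_reference_instructs_fallback(self):
        cm = _matrix(np.array([[0, 5], [3, 0]]))
        with pytest.raises(nd.EmptyReferenceError, match="fallback"):
            nd.size_factors(cm)
        f = nd.size_factors(cm, fallback=True)
        assert (f > 0).all()


class TestNormalize:
    def test_unit_factors_identity(self, small_random_matrix):
        f = pd.Series(1.0, index=list(small_random_matrix.sample_ids))
        norm = nd.normalize(small_random_matrix, f)
        assert np.array_equal(norm.to_numpy(), small_random_matrix.counts)

    def test_doubling_factor_halves_column(self, small_random_matrix):
        f = pd.Series(1.0, index=list(small_random_matrix.sample_ids))
        base = nd.normalize(small_random_matrix, f)
        f["s2"] = 2.0
        halved = nd.normalize(small_random_matrix, f)
        assert np.allclose(halved["s2"], base["s2"] / 2)

    def test_scaled_pair_columns_equalized(self):
        a = np.array([[10], [20], [5], [100]])
        cm = _matrix(np.hstack([a, 2 * a]))
        norm = nd.normalize(cm, nd.size_factors(cm))
        assert np.allclose(norm["s0"].sum(), norm["s1"].sum())

    def test_missing_factor_raises(self, small_random_matrix):
        with pytest.raises(ValidationError, match="missing"):
            nd.normalize(small_random_matrix, {"s0": 1.0})


class TestBHAdjust:
    def test_single_p(self):
        assert nd.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_evaluated_step_up(self):
        # step-up: 0.04*4/4, then min-accumulated from the top
        assert np.allclose(nd.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            nd.bh_adjust([0.1, np.nan])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        ours = nd.bh_adjust(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        ours = nd.bh_adjust(p)
        theirs = nd.bh_adjust(shuffled)
        assert np.allclose([ours[i] for i in perm], theirs, atol=1e-12)

    def test_bounded_by_one(self):
        out = nd.bh_adjust([0.5, 0.9, 0.99, 1.0])
        assert (out <= 1.0).all()


@pytest.fixture(scope="module")
def null_result():
    rng = np.random.default_rng(42)
    size = 1 / 0.05
    counts = rng.negative_binomial(size, size / (size + 100.0), size=(2000, 8))
    cm = _matrix(counts)
    groups = ([f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)])
    return nd.nb_wald_test(cm, None, groups, dispersion_mode="pooled", fallback=True)


class TestNbWaldTest:
    def test_identical_groups_null(self):
        counts = np.tile([[10], [50], [200], [7], [31]], (1, 6))
        cm = _matrix(counts)
        res = nd.nb_wald_test(
            cm, None, (["s0", "s1", "s2"], ["s3", "s4", "s5"]), fallback=True
        )
        assert np.allclose(res.log2fc, 0.0, atol=1e-12)
        assert np.allclose(res.p_value, 1.0, atol=1e-9)

    def test_type_one_error_calibrated(self, null_result):
        rate = (null_result.p_value <= 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_power_on_planted_fold4(self):
        rng = np.random.default_rng(7)
        size = 1 / 0.05
        mu_a = np.full(2000, 100.0)
        mu_b = mu_a.copy()
        mu_b[:200] *= 4
        counts = np.hstack(
            [
                rng.negative_binomial(size, size / (size + mu_a[:, None]), (2000, 4)),
                rng.negative_binomial(size, size / (size + mu_b[:, None]), (2000, 4)),
            ]
        )
        cm = _matrix(counts)
        res = nd.nb_wald_test(
            cm, None, ([f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]),
            dispersion_mode="pooled", fallback=True,
        )
        assert (res.fdr.iloc[:200] <= 0.1).mean() >= 0.9

    def test_swap_negates_log2fc_preserves_p(self, small_random_matrix):
        cm = small_random_matrix
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = nd.nb_wald_test(cm, None, (a, b), fallback=True)
        rev = nd.nb_wald_test(cm, None, (b, a), fallback=True)
        assert np.allclose(fwd.log2fc, -rev.log2fc, atol=1e-10)
        assert np.allclose(fwd.p_value, rev.p_value, atol=1e-10)

    def test_all_zero_gene_sentinel(self):
        counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        cm = _matrix(counts)
        res = nd.nb_wald_test(cm, None, (["s0", "s1"], ["s2", "s3"]), fallback=True)
        row = res[res.gene_id == "g0"].iloc[0]
        assert row.status == "all_zero"
        assert row.p_value == 1.0
        assert np.isnan(row.log2fc)

    def test_small_group_rejected(self, small_random_matrix):
        with pytest.raises(ValidationError):
            nd.nb_wald_test(small_random_matrix, None, (["s0"], ["s1", "s2"]))

    def test_overlapping_groups_rejected(self, small_random_matrix):
        with pytest.raises(ValidationError):
            nd.nb_wald_test(small_random_matrix, None, (["s0", "s1"], ["s1", "s2"]))


@pytest.fixture(scope="module")
def noisefree():
    design = sd.SimulationDesign(rng_seed=0, nb_dispersion=0.0, library_size_log_sd=0.0)
    programs = sd.default_programs(rng_seed=0)
    cm, sheet, truth = sd.simulate_treatment(design, programs)
    table = nd.fold_change_table(cm, sheet, RunConfig(), design.day_match)
    return design, truth, table


class TestFoldChangeTable:
    def test_unresponsive_gene_flat(self, noisefree):
        design, truth, table = noisefree
        gene = truth[truth.treatment_class == "unresponsive"].gene_id.iloc[0]
        sub = table[table.gene_id == gene]
        assert np.allclose(sub.log2fc, 0.0, atol=0.1)

    def test_day0_forced_zero(self, noisefree):
        _, truth, table = noisefree
        plast = truth[truth.treatment_class == "plasticity_up"].gene_id
        d0 = table[(table.timepoint_days == 0) & table.gene_id.isin(plast)]
        assert (d0.log2fc == 0).all()

    def test_plasticity_profile_monotone(self, noisefree):
        _, truth, table = noisefree
        gene = truth[truth.treatment_class == "plasticity_up"].gene_id.iloc[0]
        hu = table[(table.gene_id == gene) & (table.context == "HU")].sort_values(
            "timepoint_days"
        )
        assert (np.diff(hu.log2fc) >= -1e-9).all()

    def test_missing_control_raises(self, default_programs):
        design = sd.SimulationDesign(rng_seed=0)
        cm, sheet, _ = sd.simulate_treatment(design, default_programs[:5])
        bad_match = {"HU": {0: 99.0, 1: 99.0, 3: 99.0, 7: 99.0}}
        with pytest.raises(ValidationError, match="control"):
            nd.fold_change_table(cm, sheet, RunConfig(), bad_match)
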