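"""Median-of-ratios normalization and a simplified NB Wald test with BH FDR.

This is a self-contained replacement for the delegated normalization /
differential-expression step: size factors follow the classic
median-of-ratios construction, the test models counts as NB with
``var = mu + dispersion * mu**2``, estimates dispersion by the method of
moments (optionally shrunk to a mean--dispersion trend across genes), and
computes a two-sided Wald p-value against the normal reference.  No
shrinkage priors, Cook's filtering or independent filtering are applied.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_core import CountMatrix, RunConfig, SampleSheet, ValidationError

DISPERSION_FLOOR = 1e-8


class EmptyReferenceError(ValueError):
    """No gene is nonzero in every sample.

    Re-run with ``fallback=True`` to use the positive-counts pseudo-reference
    (geometric means over nonzero entries only).
    """


# ---------------------------------------------------------------------------
# size factors / normalization
# ---------------------------------------------------------------------------


def size_factors(matrix: CountMatrix, fallback: bool = False) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with no zero count in any sample; each sample's
    factor is the median over reference genes of count / geometric-mean-
    across-samples.  With ``fallback=True`` the geometric mean is taken over
    positive entries only and each sample's median over its own positive
    counts, which tolerates sparse designs.
    """
    counts = matrix.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_positive = (counts > 0).all(axis=1)
    if not fallback:
        if not all_positive.any():
            raise EmptyReferenceError(
                "no gene has nonzero counts in every sample; "
                "re-run with the pseudo-reference fallback flag"
            )
        ref_log_mean = logc[all_positive].mean(axis=1)
        # median taken over linear ratios (even-sized reference sets average
        # the two middle ratios arithmetically, not geometrically)
        ratios = np.exp(logc[all_positive] - ref_log_mean[:, None])
        factors = np.median(ratios, axis=0)
    else:
        any_positive = (counts > 0).any(axis=1)
        if not any_positive.any():
            raise EmptyReferenceError("matrix is all zero")
        npos = (counts > 0).sum(axis=1)
        log_geo = np.where(
            any_positive,
            np.where(counts > 0, logc, 0.0).sum(axis=1) / np.maximum(npos, 1),
            np.nan,
        )
        factors = np.empty(matrix.n_samples)
        for j in range(matrix.n_samples):
            use = (counts[:, j] > 0) & any_positive
            if not use.any():
                raise EmptyReferenceError(
                    f"sample {matrix.sample_ids[j]!r} has no positive counts"
                )
            factors[j] = np.median(np.exp(logc[use, j] - log_geo[use]))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValidationError("size factor estimation produced non-positive factors")
    return pd.Series(factors, index=list(matrix.sample_ids), name="size_factor")


def normalize(matrix: CountMatrix, factors: Mapping[str, float]) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [s for s in matrix.sample_ids if s not in factors]
    if missing:
        raise ValidationError(f"size factors missing for samples: {missing}")
    f = np.array([factors[s] for s in matrix.sample_ids], dtype=float)
    if (f <= 0).any():
        raise ValidationError("size factors must be strictly positive")
    return pd.DataFrame(
        matrix.counts / f[np.newaxis, :],
        index=list(matrix.gene_ids),
        columns=list(matrix.sample_ids),
    )


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing fdr along the sorted p-values
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _moments_dispersion(
    norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion pooled over the two groups."""
    ya, yb = norm[:, idx_a], norm[:, idx_b]
    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)
    var_a = ya.var(axis=1, ddof=1)
    var_b = yb.var(axis=1, ddof=1)
    na, nb = len(idx_a), len(idx_b)
    # pooled excess variance: weight within-group moment estimates by df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a) / mu_a**2
        alpha_b = (var_b - mu_b) / mu_b**2
    alpha_a = np.where(mu_a > 0, alpha_a, np.nan)
    alpha_b = np.where(mu_b > 0, alpha_b, np.nan)
    wa, wb = na - 1, nb - 1
    stacked = np.vstack([alpha_a, alpha_b])
    weights = np.array([wa, wb], dtype=float)[:, None] * ~np.isnan(stacked)
    vals = np.where(np.isnan(stacked), 0.0, stacked)
    with np.errstate(invalid="ignore"):
        alpha = (vals * weights).sum(axis=0) / weights.sum(axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR), mu_a, mu_b


def _trend_dispersion(alpha: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu across genes and evaluate the trend.

    Robustified by one round of trimming; falls back to the median when the
    fit is degenerate.  Used by the ``pooled`` mode, which shares dispersion
    information across genes the way small-replicate designs require.
    """
    use = (base_mean > 0) & np.isfinite(alpha)
    if use.sum() < 10:
        med = float(np.median(alpha[use])) if use.any() else DISPERSION_FLOOR
        return np.full_like(alpha, max(med, DISPERSION_FLOOR))
    x = 1.0 / base_mean[use]
    y = alpha[use]
    for _ in range(2):
        A = np.vstack([np.ones_like(x), x]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fit = A @ coef
        resid = np.abs(y - fit)
        keep = resid <= 3 * np.median(resid) + 1e-12
        if keep.all() or keep.sum() < 10:
            break
        x, y = x[keep], y[keep]
    a0, a1 = coef
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(base_mean > 0, base_mean, np.inf)
    trend = np.where(np.isfinite(trend), trend, np.median(y))
    return np.maximum(trend, DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------


def nb_wald_test(
    matrix: CountMatrix,
    sheet: Optional[SampleSheet],
    contrast: Tuple[Sequence[str], Sequence[str]],
    dispersion_mode: str = "pooled",
    factors: Optional[Mapping[str, float]] = None,
    fallback: bool = False,
    fold_pseudo: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test; group B over group A (treated over control).

    Returns a frame with base_mean, log2fc, se_log2fc, p_value, fdr and a
    status column; genes all-zero in both groups carry log2fc = NaN and the
    p = 1 sentinel so downstream set totals are conserved.
    """
    group_a, group_b = [list(g) for g in contrast]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each contrast group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("contrast groups must be disjoint")
    if dispersion_mode not in ("moments", "pooled"):
        raise ValidationError(f"unknown dispersion_mode {dispersion_mode!r}")
    sub = matrix.subset_samples(group_a + group_b)
    if factors is None:
        factors = size_factors(sub, fallback=fallback)
    norm = normalize(sub, factors).to_numpy()
    idx_a = np.arange(len(group_a))
    idx_b = np.arange(len(group_a), len(group_a) + len(group_b))
    na, nb = len(group_a), len(group_b)

    alpha, mu_a, mu_b = _moments_dispersion(norm, idx_a, idx_b)
    base_mean = norm.mean(axis=1)
    if dispersion_mode == "pooled":
        alpha = _trend_dispersion(alpha, base_mean)

    mu_a_p = mu_a + fold_pseudo
    mu_b_p = mu_b + fold_pseudo
    log2fc = np.log2(mu_b_p / mu_a_p)
    # delta-method variance of log2 of a NB group mean
    var_log_a = (mu_a_p + alpha * mu_a_p**2) / (na * mu_a_p**2)
    var_log_b = (mu_b_p + alpha * mu_b_p**2) / (nb * mu_b_p**2)
    se = np.sqrt(var_log_a + var_log_b) / np.log(2)

    from scipy.stats import norm as normal_dist

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * normal_dist.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    all_zero = (mu_a == 0) & (mu_b == 0)
    log2fc = np.where(all_zero, np.nan, log2fc)
    se = np.where(all_zero, np.nan, se)
    p = np.where(all_zero, 1.0, p)
    fdr = bh_adjust(p)

    return pd.DataFrame(
        {
            "gene_id": list(matrix.gene_ids),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p_value": p,
            "fdr": fdr,
            "status": np.where(all_zero, "all_zero", "ok"),
        }
    )


# ---------------------------------------------------------------------------
# treatment fold table
# ---------------------------------------------------------------------------


def fold_change_table(
    matrix: CountMatrix,
    sheet: SampleSheet,
    config: RunConfig,
    design_day_match: Optional[Mapping[str, Mapping[float, float]]] = None,
    factors: Optional[Mapping[str, float]] = None,
    fallback: bool = True,
) -> pd.DataFrame:
    """Per-gene log2 fold of each treated (context, timepoint) vs matched control.

    The control match defaults to the closest starvation day; a day-match map
    can be supplied.  Time-0 log2 folds are fixed at 0 by convention.
    Returns a tidy frame: gene_id, context, timepoint_days, log2fc, fold.
    """
    treated = [s for s in sheet if s.experiment == "treatment" and s.condition != "control"]
    controls = [s for s in sheet if s.experiment == "treatment" and s.condition == "control"]
    if not treated or not controls:
        raise ValidationError("fold_change_table needs a treatment design with controls")
    control_days = sorted({s.timepoint_days for s in controls})
    if factors is None:
        ids = [s.sample_id for s in sheet if s.experiment == "treatment"]
        factors = size_factors(matrix.subset_samples(ids), fallback=fallback)
    covered = list(factors.index) if isinstance(factors, pd.Series) else list(factors.keys())
    norm = normalize(matrix.subset_samples(covered), factors)

    def matched_control_day(context: str, day: float) -> float:
        if design_day_match and context in design_day_match and day in design_day_match[context]:
            return design_day_match[context][day]
        return min(control_days, key=lambda d: (abs(d - day), d))

    rows = []
    grid = sorted({(s.condition, s.timepoint_days) for s in treated})
    gene_ids = list(matrix.gene_ids)
    for context, day in grid:
        t_ids = [s.sample_id for s in treated if s.condition == context and s.timepoint_days == day]
        c_day = matched_control_day(context, day)
        c_ids = [s.sample_id for s in controls if s.timepoint_days == c_day]
        if not c_ids:
            raise ValidationError(f"no matched control for {context} day {day:g}")
        mu_t = norm[t_ids].mean(axis=1).to_numpy()
        mu_c = norm[c_ids].mean(axis=1).to_numpy()
        if day == 0:
            log2fc = np.zeros(len(gene_ids))  # time-0 extrapolated to 0 by convention
        else:
            log2fc = np.log2((mu_t + config.fold_pseudo) / (mu_c + config.fold_pseudo))
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "context": context,
                    "timepoint_days": day,
                    "log2fc": log2fc,
                    "fold": 2.0 ** log2fc,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def terminal_contrasts(
    sheet: SampleSheet,
    day_match: Optional[Mapping[str, Mapping[float, float]]] = None,
) -> Dict[str, Tuple[list, list]]:
    """(control ids, treated ids) for the terminal timepoint of each context."""
    out = {}
    controls = [s for s in sheet if s.experiment == "treatment" and s.condition == "control"]
    control_days = sorted({s.timepoint_days for s in controls})
    for context in ("HU", "HS", "Col"):
        arm = [s for s in sheet if s.condition == context]
        if not arm:
            continue
        final = max(s.timepoint_days for s in arm)
        if day_match and context in day_match and final in day_match[context]:
            c_day = day_match[context][final]
        else:
            c_day = min(control_days, key=lambda d: (abs(d - final), d))
        t_ids = [s.sample_id for s in arm if s.timepoint_days == final]
        c_ids = [s.sample_id for s in controls if s.timepoint_days == c_day]
        out[context] = (c_ids, t_ids)
    return out
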