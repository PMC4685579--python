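"""Classification of axial expression profiles over (H, R1, R3, R4, F).

The verbal pattern taxonomy (apical, basal, foot-restricted, bipolar,
graded in either direction, apolar, ubiquitous) is encoded as a
deterministic rule cascade on the max-normalized profile.  All thresholds
live in :class:`~hydracross.io_core.RunConfig`; ``ambiguous`` is a valid
outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix, RunConfig, SampleSheet, SPATIAL_REGIONS, ValidationError
from .normalize_de import normalize, size_factors

PATTERNS = (
    "apolar",
    "ubiquitous",
    "apical",
    "basal",
    "foot_restricted",
    "bipolar",
    "graded_apical_to_basal",
    "graded_basal_to_apical",
    "undetected",
    "ambiguous",
)


@dataclass(frozen=True)
class SpatialProfile:
    gene_id: str
    region_means: np.ndarray  # ordered (H, R1, R3, R4, F)
    region_cv: np.ndarray
    detected: bool
    n_replicates: int = 3

    def __post_init__(self):
        rm = np.asarray(self.region_means, dtype=float)
        if rm.shape != (5,):
            raise ValidationError(f"{self.gene_id}: region_means must have 5 entries")
        if (rm < 0).any():
            raise ValidationError(f"{self.gene_id}: region means must be >= 0")
        object.__setattr__(self, "region_means", rm)
        object.__setattr__(self, "region_cv", np.asarray(self.region_cv, dtype=float))


@dataclass(frozen=True)
class PatternCall:
    gene_id: str
    pattern: str
    score: float


def build_profiles(
    matrix: CountMatrix,
    sheet: SampleSheet,
    factors: Optional[Mapping[str, float]] = None,
    config: Optional[RunConfig] = None,
) -> list:
    """Per-gene region means/CVs of normalized counts over replicates."""
    config = config or RunConfig()
    spatial_ids = [s.sample_id for s in sheet if s.experiment == "spatial"]
    if not spatial_ids:
        raise ValidationError("no spatial samples in sheet")
    sub = matrix.subset_samples(spatial_ids)
    if factors is None:
        factors = size_factors(sub, fallback=True)
    norm = normalize(sub, factors)
    region_cols = {}
    for region in SPATIAL_REGIONS:
        ids = [s.sample_id for s in sheet if s.experiment == "spatial" and s.condition == region]
        if len(ids) < 2:
            raise ValidationError(f"region {region}: >= 2 replicates required")
        region_cols[region] = norm[ids]

    profiles = []
    for gene in matrix.gene_ids:
        means = np.array([region_cols[r].loc[gene].mean() for r in SPATIAL_REGIONS])
        sds = np.array([region_cols[r].loc[gene].std(ddof=1) for r in SPATIAL_REGIONS])
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(means > 0, sds / means, 0.0)
        profiles.append(
            SpatialProfile(
                gene_id=gene,
                region_means=means,
                region_cv=cv,
                detected=bool(means.max() >= config.expression_floor),
                n_replicates=min(region_cols[r].shape[1] for r in SPATIAL_REGIONS),
            )
        )
    return profiles


def _graded(profile: SpatialProfile, p: np.ndarray, direction: str, config: RunConfig) -> bool:
    """Monotone-within-tolerance profile with a real end-to-end span.

    The per-step tolerance is widened by the standard errors of the two
    region means involved (in max-normalized units), so replicate noise on
    weakly expressed genes cannot break an otherwise monotone profile.  The
    interior-elevation requirement separates genuinely graded profiles from
    polar ones that collapse right after the peak; the span requirement has
    no noise slack.
    """
    se = p * profile.region_cv / np.sqrt(max(profile.n_replicates, 1))
    step_tol = config.graded_tol + se[:-1] + se[1:]
    if direction == "down":  # apical -> basal
        steps_ok = np.all(np.diff(p) <= step_tol)
        span_ok = (p[0] - p[4]) >= config.graded_span
        interior_ok = p[1] >= config.graded_interior
    else:  # basal -> apical
        steps_ok = np.all(np.diff(p) >= -step_tol)
        span_ok = (p[4] - p[0]) >= config.graded_span
        interior_ok = p[3] >= config.graded_interior
    return bool(steps_ok and span_ok and interior_ok)


def classify_pattern(profile: SpatialProfile, config: Optional[RunConfig] = None) -> PatternCall:
    """Deterministic rule cascade on the max-normalized profile.

    Order: foot_restricted -> apical -> basal -> bipolar -> graded (either
    direction) -> apolar -> ubiquitous -> ambiguous.  The score is the margin
    by which the winning rule clears its tightest threshold, clipped to [0,1].
    """
    config = config or RunConfig()
    if not profile.detected:
        return PatternCall(profile.gene_id, "undetected", 0.0)
    raw = profile.region_means
    p = raw / raw.max()
    ph, pf = p[0], p[4]
    core = p[1:4]

    def call(pattern, *margins):
        return PatternCall(profile.gene_id, pattern, float(np.clip(min(margins), 0.0, 1.0)))

    if pf == 1.0 and np.max(p[:4]) <= config.foot_off:
        return call("foot_restricted", config.foot_off - np.max(p[:4]))
    if ph == 1.0 and pf <= config.polar_off and not _graded(profile, p, "down", config):
        return call("apical", config.polar_off - pf)
    if pf == 1.0 and ph <= config.polar_off and not _graded(profile, p, "up", config):
        return call("basal", config.polar_off - ph)
    if min(ph, pf) >= config.bipolar_min and core.min() <= config.trough_frac * min(ph, pf):
        return call(
            "bipolar",
            min(ph, pf) - config.bipolar_min,
            config.trough_frac * min(ph, pf) - core.min(),
        )
    if _graded(profile, p, "down", config):
        return call("graded_apical_to_basal", (p[0] - p[4]) - config.graded_span)
    if _graded(profile, p, "up", config):
        return call("graded_basal_to_apical", (p[4] - p[0]) - config.graded_span)
    if core.max() == 1.0 and max(ph, pf) <= config.apolar_ext:
        return call("apolar", config.apolar_ext - max(ph, pf))
    if p.min() >= config.ubiquitous_min:
        return call("ubiquitous", p.min() - config.ubiquitous_min)
    return PatternCall(profile.gene_id, "ambiguous", 0.0)


def classify_all(profiles: Sequence[SpatialProfile], config: Optional[RunConfig] = None) -> pd.DataFrame:
    config = config or RunConfig()
    calls = [classify_pattern(pr, config) for pr in profiles]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "pattern": [c.pattern for c in calls],
            "score": [c.score for c in calls],
        }
    )


def score_spatial_recovery(calls: pd.DataFrame, truth: pd.DataFrame):
    """Confusion matrix plus per-class sensitivity/precision against truth."""
    missing = set(calls["gene_id"]) - set(truth["gene_id"])
    if missing:
        raise ValidationError(f"genes absent from truth table: {sorted(missing)[:5]}")
    merged = calls.merge(truth[["gene_id", "spatial_class"]], on="gene_id")
    confusion = pd.crosstab(merged["spatial_class"], merged["pattern"])
    classes = sorted(merged["spatial_class"].unique())
    rows = []
    for cls in classes:
        in_class = merged["spatial_class"] == cls
        called = merged["pattern"] == cls
        tp = int((in_class & called).sum())
        sens = tp / in_class.sum() if in_class.any() else np.nan
        prec = tp / called.sum() if called.any() else np.nan
        rows.append(
            {"class": cls, "n_true": int(in_class.sum()), "sensitivity": sens, "precision": prec}
        )
    metrics = pd.DataFrame(rows)
    accuracy = float((merged["spatial_class"] == merged["pattern"]).mean())
    return confusion, metrics, accuracy
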