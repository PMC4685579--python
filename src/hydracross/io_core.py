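"""Core data model and file I/O shared by every pipeline stage.

Count matrices are raw mapped-read counts (gene x sample, non-negative
integers).  Sample sheets describe one of the three supported designs:

* ``spatial``   -- five axial regions H, R1, R3, R4, F (no R2 exists);
* ``treatment`` -- body-column samples from control / HU / HS / Col arms,
  with a ``timepoint_days`` column;
* ``celltype``  -- FACS fractions ecto / endo / icell plus unsorted tissue.

All tabular output goes through :func:`write_report`, which produces
deterministic, byte-stable TSV files.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hydracross")

PIPELINE_VERSION = "0.1.0"

SPATIAL_REGIONS = ("H", "R1", "R3", "R4", "F")
TREATMENT_CONDITIONS = ("control", "HU", "HS", "Col")
CELLTYPE_CONDITIONS = ("ecto", "endo", "icell", "unsorted")
EXPERIMENTS = ("spatial", "treatment", "celltype")

CONDITION_VOCABULARY = {
    "spatial": SPATIAL_REGIONS,
    "treatment": TREATMENT_CONDITIONS,
    "celltype": CELLTYPE_CONDITIONS,
}

ANNOTATION_CATEGORIES = ("NG", "NT", "other")


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class FormatError(ValueError):
    """File is structurally malformed."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Immutable gene x sample matrix of non-negative integer read counts."""

    gene_ids: tuple
    sample_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if np.issubdtype(counts.dtype, np.floating):
            bad = ~np.isfinite(counts)
            if bad.any():
                raise ValidationError(
                    f"non-finite count at {_first_cell(self, bad)}"
                )
            if not np.all(counts == np.floor(counts)):
                bad = counts != np.floor(counts)
                raise ValidationError(
                    f"non-integer count at {_first_cell(self, bad)}"
                )
        elif not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError(f"counts dtype {counts.dtype} is not numeric")
        if (counts < 0).any():
            bad = counts < 0
            raise ValidationError(f"negative count at {_first_cell(self, bad)}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, tuple(sample_ids), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())


def _duplicates(ids: Sequence[str]) -> set:
    seen, dup = set(), set()
    for i in ids:
        (dup if i in seen else seen).add(i)
    return dup


def _first_cell(cm: CountMatrix, bad: np.ndarray) -> str:
    g, s = np.argwhere(bad)[0]
    return f"(gene={cm.gene_ids[g]!r}, sample={cm.sample_ids[s]!r})"


def read_count_matrix(
    path,
    fmt: str = "tsv",
    genes_path=None,
    samples_path=None,
) -> CountMatrix:
    """Read a count matrix from ``tsv`` or ``mtx-triplet`` format.

    TSV: header row of sample ids, first column gene ids.  MatrixMarket
    coordinate files use sidecar id lists ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` unless paths are given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except Exception as exc:  # malformed header/body
            raise FormatError(f"cannot parse {path} as TSV count matrix: {exc}")
        if df.empty and df.columns.empty:
            raise FormatError(f"{path}: no sample columns found")
        if df.isna().any().any():
            gene = df.index[df.isna().any(axis=1)][0]
            raise ValidationError(f"NaN count in row {gene!r} of {path}")
        return CountMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy())
    if fmt == "mtx-triplet":
        from scipy.io import mmread

        stem = path.with_suffix("")
        genes_path = Path(genes_path) if genes_path else Path(str(stem) + ".genes.txt")
        samples_path = Path(samples_path) if samples_path else Path(str(stem) + ".samples.txt")
        gene_ids = [l.strip() for l in genes_path.read_text().splitlines() if l.strip()]
        sample_ids = [l.strip() for l in samples_path.read_text().splitlines() if l.strip()]
        try:
            mat = mmread(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as MatrixMarket: {exc}")
        dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        return CountMatrix(tuple(gene_ids), tuple(sample_ids), dense)
    raise ValueError(f"unknown count-matrix format {fmt!r}")


def write_count_matrix(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        cm.to_dataframe().to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
        return
    if fmt == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(str(stem) + ".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(str(stem) + ".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
        return
    raise ValueError(f"unknown count-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    sample_id: str
    experiment: str
    condition: str
    replicate: int
    timepoint_days: Optional[float] = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown experiment {self.experiment!r} "
                f"(expected one of {EXPERIMENTS})"
            )
        vocab = CONDITION_VOCABULARY[self.experiment]
        if self.condition not in vocab:
            raise ValidationError(
                f"sample {self.sample_id!r}: condition {self.condition!r} not in the "
                f"{self.experiment} design vocabulary {vocab}"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )
        if self.timepoint_days is not None and self.timepoint_days < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint_days must be non-negative"
            )


class SampleSheet:
    """Ordered collection of :class:`Sample` records with a closed vocabulary."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample ids: {sorted(_duplicates(ids))}")

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self):
        return [s.sample_id for s in self.samples]

    @property
    def experiments(self):
        return sorted({s.experiment for s in self.samples})

    def select(self, **criteria) -> list:
        """Sample ids matching all criteria (field=value or field=set)."""
        out = []
        for s in self.samples:
            ok = True
            for key, want in criteria.items():
                val = getattr(s, key)
                if isinstance(want, (set, frozenset, list, tuple)):
                    ok = val in want
                else:
                    ok = val == want
                if not ok:
                    break
            if ok:
                out.append(s.sample_id)
        return out

    def groups(self, keys=("experiment", "condition", "timepoint_days")) -> dict:
        out: dict = {}
        for s in self.samples:
            k = tuple(getattr(s, key) for key in keys)
            out.setdefault(k, []).append(s.sample_id)
        return out

    def check_replicates(self, minimum: int = 2) -> None:
        for key, ids in self.groups().items():
            if len(ids) < minimum:
                raise ValidationError(
                    f"group {key} has {len(ids)} replicate(s); {minimum} required"
                )

    def check_matches(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples absent from sheet: {sorted(missing)}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "experiment": s.experiment,
                    "condition": s.condition,
                    "timepoint_days": s.timepoint_days,
                    "replicate": s.replicate,
                }
                for s in self.samples
            ]
        )


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "experiment", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        tp = row.get("timepoint_days")
        tp = None if tp is None or (isinstance(tp, float) and np.isnan(tp)) else float(tp)
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                experiment=str(row["experiment"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                timepoint_days=tp,
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sheet.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    category: str
    family_label: Optional[str] = None

    def __post_init__(self):
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValidationError(
                f"annotation for {self.gene_id!r}: category {self.category!r} "
                f"not in {ANNOTATION_CATEGORIES}"
            )


def read_annotation(path) -> dict:
    """Read gene annotation TSV (gene_id, category[, family_label]) to a dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "category" not in df.columns:
        raise FormatError(f"{path}: annotation needs gene_id and category columns")
    out = {}
    for _, row in df.iterrows():
        fam = row.get("family_label")
        fam = None if fam is None or (isinstance(fam, float) and np.isnan(fam)) else str(fam)
        ann = GeneAnnotation(str(row["gene_id"]), str(row["category"]), fam)
        out[ann.gene_id] = ann
    return out


def match_annotation(annotation: Mapping[str, GeneAnnotation], cm: CountMatrix) -> dict:
    """Restrict an annotation to genes present in the matrix; extras are logged."""
    present = set(cm.gene_ids)
    dropped = sorted(set(annotation) - present)
    if dropped:
        logger.info(
            "annotation: %d gene(s) absent from matrix, ignored (e.g. %s)",
            len(dropped), dropped[:3],
        )
    return {g: a for g, a in annotation.items() if g in present}


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, overridable from file or CLI."""

    # signature thresholds
    up_fold: float = 2.0            # minimal linear up-fold per context
    down_retention: float = 0.10    # final/control ratio counting as ">90% reduction"
    fdr_alpha: float = 0.1
    min_contexts: int = 2           # contexts required for a plasticity candidate
    stable_floor: float = 0.8       # "stable or elevated" floor for gland calls

    # spatial classifier
    expression_floor: float = 5.0   # max region mean below this => undetected
    foot_off: float = 0.2           # off-level for restricted patterns
    polar_off: float = 0.3          # far-extremity ceiling for apical/basal
    bipolar_min: float = 0.6        # minimum extremity level for bipolar
    trough_frac: float = 0.5        # central trough relative to extremities
    graded_tol: float = 0.1         # per-step monotonicity tolerance
    graded_span: float = 0.4        # minimum end-to-end drop for graded calls
    graded_interior: float = 0.45   # minimum near-peak interior level for graded
    apolar_ext: float = 0.5         # extremity ceiling for apolar
    ubiquitous_min: float = 0.5     # profile floor for ubiquitous

    # celltype composition
    specific_fraction: float = 0.65
    shared_floor: float = 0.15
    epithelial_balance: float = 0.25
    pseudo_count: float = 0.5       # inside-log pseudo for geometric means

    # differential expression
    fold_pseudo: float = 0.5        # pseudo normalized count in fold ratios
    dispersion_mode: str = "pooled"
    kinetics_tol: float = 0.25      # slack for the monotone time-course flag

    rng_seed: int = 0

    def __post_init__(self):
        positive = {
            "up_fold": self.up_fold,
            "down_retention": self.down_retention,
            "fdr_alpha": self.fdr_alpha,
            "expression_floor": self.expression_floor,
            "specific_fraction": self.specific_fraction,
            "shared_floor": self.shared_floor,
            "pseudo_count": self.pseudo_count,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValidationError(f"config {name} must be strictly positive")
        if not self.down_retention < 1:
            raise ValidationError("config down_retention must be < 1")
        if not 1 <= self.min_contexts <= 3:
            raise ValidationError("config min_contexts must be in [1, 3]")
        if self.dispersion_mode not in ("moments", "pooled"):
            raise ValidationError("config dispersion_mode must be moments or pooled")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.6g"


def write_report(results, path, config: Optional[RunConfig] = None) -> None:
    """Write a stage output table as a deterministic TSV.

    The header comments name the pipeline version and, when given, every
    RunConfig value, so a report is self-describing.  Identical inputs and
    config produce byte-identical files.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, pd.Series):
        df = results.rename_axis("gene_id").reset_index()
    else:
        df = pd.DataFrame(list(results))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(f"# hydracross version={PIPELINE_VERSION}\n")
    if config is not None:
        for key, value in sorted(config.to_dict().items()):
            buf.write(f"# config {key}={value}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    path.write_text(buf.getvalue())


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
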