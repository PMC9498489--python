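"""Input/output, domain types, configuration and logging.

The pipeline operates on three plain-text artifacts:

* a gene x sample table of non-negative integer read counts (TSV, genes in
  rows, a header row of sample ids, first column of gene ids);
* a sample metadata table (TSV) with columns ``sample_id``, ``diagnosis``
  (control / UC / CD), ``age_group`` (adult / child) and ``activity``
  (integer disease-activity grade, 0 = remission .. 4 = active flare);
* a TOML run configuration in which every tunable of the analysis is a key,
  so that an empty file reproduces the reference analysis exactly.

Matrices are desk-scale (tens of thousands of genes by a few hundred
samples) and are held dense.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from contextlib import contextmanager
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("translasso")

DIAGNOSES = ("control", "UC", "CD")
AGE_GROUPS = ("adult", "child")
ACTIVITY_RANGE = (0, 4)


class TranslassoError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TranslassoError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(TranslassoError):
    """An in-memory object violates a documented invariant."""


@contextmanager
def stage(name: str, **dims):
    """Log one structured line per pipeline stage with dimensions and time."""
    t0 = time.perf_counter()
    yield
    elapsed = time.perf_counter() - t0
    extra = " ".join(f"{k}={v}" for k, v in dims.items())
    logger.info("stage=%s elapsed=%.3fs %s", name, elapsed, extra)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with identifiers.

    Invariants: counts are non-negative integers; gene and sample ids are
    unique; array dimensions match the id lists.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Per-sample phenotype labels aligned with a :class:`CountMatrix`.

    ``activity`` follows a 0 (remission) .. 4 (active flare) clinical grading;
    controls are graded 0 by definition.
    """

    sample_ids: list[str]
    diagnosis: np.ndarray  # str array
    age_group: np.ndarray  # str array
    activity: np.ndarray  # int array in [0, 4]

    def __post_init__(self):
        self.diagnosis = np.asarray(self.diagnosis, dtype=object)
        self.age_group = np.asarray(self.age_group, dtype=object)
        self.activity = np.asarray(self.activity, dtype=np.int64)
        n = len(self.sample_ids)
        if not (len(self.diagnosis) == len(self.age_group) == len(self.activity) == n):
            raise ValidationError("sample table column lengths differ")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in metadata")
        bad = set(self.diagnosis) - set(DIAGNOSES)
        if bad:
            raise ValidationError(
                f"unknown diagnosis labels {sorted(bad)}; allowed: {list(DIAGNOSES)}"
            )
        bad = set(self.age_group) - set(AGE_GROUPS)
        if bad:
            raise ValidationError(
                f"unknown age_group labels {sorted(bad)}; allowed: {list(AGE_GROUPS)}"
            )
        lo, hi = ACTIVITY_RANGE
        if ((self.activity < lo) | (self.activity > hi)).any():
            raise ValidationError(f"activity grades must lie in [{lo}, {hi}]")
        ctrl_active = (self.diagnosis == "control") & (self.activity != 0)
        if ctrl_active.any():
            sid = self.sample_ids[int(np.argmax(ctrl_active))]
            raise ValidationError(f"control sample {sid!r} has nonzero activity grade")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def is_case(self) -> np.ndarray:
        return self.diagnosis != "control"


_LAMBDA_GRID_DEFAULT = tuple(round(0.01 * k, 2) for k in range(1, 41))


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, defaulting to the reference settings.

    The all-defaults configuration is: drop genes with total count <= 10,
    median-of-ratios size factors, log2(count/s + 1) transform, preselection
    of transcripts carrying 95% of squared-loading mass on the first three
    principal components, pure lasso (alpha = 1) logistic regression with
    per-coefficient bounds +/-0.1 over lambda in 0.01..0.40 (step 0.01),
    tenfold stratified cross-validation, median AUC over folds with
    AUC > 0.5 for lambda selection, and 90% confidence intervals.
    """

    filter_threshold: int = 10
    log_offset: float = 1.0
    n_pcs: int = 3
    pc_variance_fraction: float = 0.95
    alpha: float = 1.0
    lambda_grid: tuple[float, ...] = _LAMBDA_GRID_DEFAULT
    coef_lower: float = -0.1
    coef_upper: float = 0.1
    n_folds: int = 10
    auc_null_cutoff: float = 0.5
    lambda_tolerance: float = 0.01
    ci_level: float = 0.90
    rng_seed: int = 0
    nested_preselection: bool = False
    # gap-filling decisions, surfaced as configuration
    pca_include_controls: bool = True
    grade2_policy: str = "exclude"  # exclude | active | remission

    def __post_init__(self):
        if self.filter_threshold < 0:
            raise ValidationError("filter_threshold: must be >= 0")
        if self.log_offset <= 0:
            raise ValidationError("log_offset: must be > 0")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs: must be >= 1")
        if not 0 < self.pc_variance_fraction <= 1:
            raise ValidationError("pc_variance_fraction: must lie in (0, 1]")
        if self.alpha != 1:
            raise ValidationError("alpha: only the pure lasso (alpha = 1) is supported")
        grid = tuple(float(v) for v in self.lambda_grid)
        if len(grid) == 0 or any(v <= 0 for v in grid):
            raise ValidationError("lambda_grid: values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("lambda_grid: must be strictly increasing")
        object.__setattr__(self, "lambda_grid", grid)
        if not self.coef_lower < 0:
            raise ValidationError("coef_lower: must be negative")
        if not self.coef_upper > 0:
            raise ValidationError("coef_upper: must be positive")
        if self.n_folds < 2:
            raise ValidationError("n_folds: must be >= 2")
        if not 0 <= self.auc_null_cutoff < 1:
            raise ValidationError("auc_null_cutoff: must lie in [0, 1)")
        if self.lambda_tolerance < 0:
            raise ValidationError("lambda_tolerance: must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level: must lie in (0, 1)")
        if self.grade2_policy not in ("exclude", "active", "remission"):
            raise ValidationError(
                "grade2_policy: must be one of exclude, active, remission"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV into a validated :class:`CountMatrix`.

    The first column holds gene ids, the header row holds sample ids.
    Malformed cells raise :class:`ParseError` naming row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path.name}: non-numeric count {df.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    arr = numeric.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path.name}: negative count at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    if not np.all(arr == np.floor(arr)):
        i, j = np.argwhere(arr != np.floor(arr))[0]
        raise ParseError(
            f"{path.name}: non-integer count at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return CountMatrix(gene_ids, sample_ids, arr.astype(np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


SAMPLE_COLUMNS = ("sample_id", "diagnosis", "age_group", "activity")


def read_samples(path: str | Path, counts: CountMatrix) -> SampleTable:
    """Read the sample metadata TSV and align it to ``counts``.

    Rows are reordered to the column order of ``counts``; the metadata must
    cover exactly the samples of the count matrix.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: missing columns {sorted(missing)}")
    ids = [str(s) for s in df["sample_id"]]
    unknown = set(ids) - set(counts.sample_ids)
    if unknown:
        raise ValidationError(
            f"samples {sorted(unknown)} absent from the count matrix"
        )
    absent = set(counts.sample_ids) - set(ids)
    if absent:
        raise ValidationError(
            f"count-matrix samples {sorted(absent)} absent from the metadata"
        )
    df = df.set_index("sample_id").loc[counts.sample_ids]
    try:
        activity = df["activity"].astype(np.int64).to_numpy()
    except ValueError as e:
        raise ParseError(f"{path.name}: non-integer activity grade ({e})") from None
    return SampleTable(
        sample_ids=list(counts.sample_ids),
        diagnosis=df["diagnosis"].to_numpy(),
        age_group=df["age_group"].to_numpy(),
        activity=activity,
    )


def write_samples(table: SampleTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "diagnosis": table.diagnosis,
            "age_group": table.age_group,
            "activity": table.activity,
        }
    ).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML pipeline configuration; missing keys take the defaults.

    Pipeline keys live at the top level of the file; a ``[simulation]``
    table, if present, is ignored here (see :func:`load_sim_spec`).
    """
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw.pop("simulation", None)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
    if "lambda_grid" in raw:
        raw["lambda_grid"] = tuple(raw["lambda_grid"])
    return PipelineConfig(**raw)


def config_with(config: PipelineConfig, **overrides) -> PipelineConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **overrides)


def write_json(obj: dict, path: str | Path) -> None:
    """Write a report dictionary deterministically (sorted keys, repr floats)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
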