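"""Gene filtering and median-of-ratios normalization.

The preprocessing chain is: drop genes whose total count across samples is
at or below the filter threshold, estimate per-sample size factors by the
median-of-ratios method on the filtered matrix, then transform to
``log2(count / s_j + offset)``.  With the default offset of 1 a zero count
maps to exactly 0, so zeros are preserved as nulls through normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, TranslassoError, ValidationError

__all__ = [
    "NormalizedMatrix",
    "filter_genes",
    "size_factors",
    "normalize_log",
    "preprocess_counts",
    "write_normalized",
    "read_normalized",
]


@dataclass
class NormalizedMatrix:
    """Log2-scale normalized expression with its per-sample size factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    size_factors: np.ndarray  # shape (n_samples,), positive

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match id lists")
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be strictly positive")


def filter_genes(cm: CountMatrix, threshold: int) -> CountMatrix:
    """Retain genes whose total count across samples exceeds ``threshold``.

    The boundary is exclusive: a gene totalling exactly ``threshold`` is
    removed.  Gene order is preserved.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    totals = cm.counts.sum(axis=1)
    keep = totals > threshold
    if not keep.any():
        raise TranslassoError(
            f"no gene has total count > {threshold}; lower filter_threshold"
        )
    gene_ids = [g for g, k in zip(cm.gene_ids, keep) if k]
    return CountMatrix(gene_ids, list(cm.sample_ids), cm.counts[keep])


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j, ``s_j`` is the median over reference genes of
    ``count[i, j] / geometric_mean_i``, where the reference set contains
    only genes with strictly positive counts in every sample (genes with
    any zero are excluded from the geometric means).
    """
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise TranslassoError(
            "size factors undefined: no gene has all-positive counts"
        )
    ref = counts[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    return np.median(ratios, axis=0)


def normalize_log(
    cm: CountMatrix, s: np.ndarray, offset: float = 1.0
) -> NormalizedMatrix:
    """Return ``log2(count / s_j + offset)`` for every cell.

    Division by the size factor precedes the offset, so at offset 1 a zero
    count maps to exactly 0 regardless of the size factor.
    """
    s = np.asarray(s, dtype=float)
    if offset <= 0:
        raise ValidationError("offset must be > 0")
    if (s <= 0).any():
        raise ValidationError("size factors must be strictly positive")
    if len(s) != len(cm.sample_ids):
        raise ValidationError("size factor length does not match samples")
    values = np.log2(cm.counts / s[None, :] + offset)
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids), values, s)


def preprocess_counts(cm: CountMatrix, threshold: int, offset: float = 1.0) -> NormalizedMatrix:
    """Filter, estimate size factors on the filtered matrix, and log-transform."""
    filtered = filter_genes(cm, threshold)
    s = size_factors(filtered)
    return normalize_log(filtered, s, offset)


def write_normalized(nm: NormalizedMatrix, path: str | Path) -> None:
    """Write values as TSV with a ``.sizefactors.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(nm.values, index=nm.gene_ids, columns=nm.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    pd.DataFrame({"sample_id": nm.sample_ids, "size_factor": nm.size_factors}).to_csv(
        path.with_suffix(".sizefactors.tsv"), sep="\t", index=False, float_format="%.10g"
    )


def read_normalized(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sf = pd.read_csv(path.with_suffix(".sizefactors.tsv"), sep="\t")
    return NormalizedMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        sf["size_factor"].to_numpy(dtype=float),
    )
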