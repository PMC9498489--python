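"""PCA loading-based transcript preselection.

Genes are standardized across samples, a PCA is computed with genes as
variables (samples as observations), and for each of the leading components
the transcripts are ranked by squared loading.  The shortest prefix whose
squared-loading mass reaches the target fraction (default 95%) of that
component's total is kept; the union over components is the preselected
transcript set.  Squared loadings are the standard sign-invariant measure
of a variable's contribution to a component, and the prefix rule keeps the
variables most representative of small-scale co-expression clusters while
reducing collinearity ahead of the penalized regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TranslassoError, ValidationError
from .preprocess import NormalizedMatrix

logger = logging.getLogger("translasso")

__all__ = ["PCASelection", "scale_genes", "pca", "select_top_transcripts", "preselect", "write_selection"]


@dataclass
class PCASelection:
    """Result of the loading-based preselection.

    ``selected_gene_ids`` is the union of the per-component prefixes with
    duplicates removed and the input gene order preserved.  ``loadings`` has
    one unit-norm column per retained component; rows follow ``gene_ids``
    (the genes that survived scaling).
    """

    gene_ids: list[str]
    loadings: np.ndarray  # (n_genes, n_pcs)
    pc_variance: np.ndarray  # explained-variance fractions, descending
    per_pc_selected: dict[int, list[str]]
    selected_gene_ids: list[str]


def scale_genes(nm: NormalizedMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    """Standardize each gene to mean 0, sd 1 (n-1 denominator) across samples.

    Returns ``(scaled, kept_gene_ids, dropped_gene_ids)``; zero-variance
    genes are dropped with a logged warning.
    """
    if len(nm.sample_ids) < 2:
        raise ValidationError("scaling requires at least 2 samples")
    mean = nm.values.mean(axis=1)
    sd = nm.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise TranslassoError("all genes have zero variance; nothing to scale")
    dropped = [g for g, k in zip(nm.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d zero-variance genes before PCA (first: %s)",
            len(dropped), dropped[0],
        )
    scaled = (nm.values[keep] - mean[keep, None]) / sd[keep, None]
    kept = [g for g, k in zip(nm.gene_ids, keep) if k]
    return scaled, kept, dropped


def pca(scaled: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the samples x genes matrix via SVD.

    ``scaled`` is genes x samples with standardized rows.  Returns
    ``(loadings, variance_fractions)`` where loadings are the unit-norm
    right singular vectors (one column per component, rows indexing genes)
    and variance fractions are sorted descending.  The sign of each
    component is fixed so its largest-magnitude loading is positive.  If the
    matrix rank is below ``n_pcs``, the available components are returned
    with a warning.
    """
    n_genes, n_samples = scaled.shape
    if n_pcs > min(n_genes, n_samples):
        raise ValidationError("n_pcs exceeds min(genes, samples)")
    A = scaled.T  # observations x variables
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(n_pcs, rank)
    if k < n_pcs:
        logger.warning("matrix rank %d < requested %d components", rank, n_pcs)
    var_frac = (s**2 / (s**2).sum())[:k]
    loadings = vt[:k].T.copy()
    for c in range(k):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    return loadings, var_frac


def select_top_transcripts(
    loadings: np.ndarray,
    pc_variance: np.ndarray,
    gene_ids: list[str],
    fraction: float,
    n_pcs: int | None = None,
) -> PCASelection:
    """Keep, per component, the minimal squared-loading prefix reaching ``fraction``.

    Genes are ranked by squared loading descending (ties broken by input
    order); the prefix is the shortest whose cumulative squared-loading mass
    is at least ``fraction`` of the component's total.  The selection is the
    union over the first ``n_pcs`` components, in input gene order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    k = loadings.shape[1] if n_pcs is None else min(n_pcs, loadings.shape[1])
    per_pc: dict[int, list[str]] = {}
    union: set[int] = set()
    for c in range(k):
        sq = loadings[:, c] ** 2
        total = sq.sum()
        order = np.argsort(-sq, kind="stable")  # stable: ties keep input order
        cum = np.cumsum(sq[order])
        target = fraction * total - 1e-12 * max(total, 1.0)
        m = int(np.searchsorted(cum, target) + 1)
        chosen = order[:m]
        per_pc[c] = [gene_ids[i] for i in chosen]
        union.update(chosen.tolist())
    selected = [g for i, g in enumerate(gene_ids) if i in union]
    return PCASelection(
        gene_ids=list(gene_ids),
        loadings=loadings[:, :k],
        pc_variance=np.asarray(pc_variance[:k]),
        per_pc_selected=per_pc,
        selected_gene_ids=selected,
    )


def preselect(
    nm: NormalizedMatrix,
    n_pcs: int,
    fraction: float,
    sample_mask: np.ndarray | None = None,
) -> PCASelection:
    """Scale, decompose and select in one step, optionally on a sample subset."""
    if sample_mask is not None:
        nm = NormalizedMatrix(
            list(nm.gene_ids),
            [s for s, m in zip(nm.sample_ids, sample_mask) if m],
            nm.values[:, np.asarray(sample_mask, dtype=bool)],
            nm.size_factors[np.asarray(sample_mask, dtype=bool)],
        )
    scaled, kept, _ = scale_genes(nm)
    loadings, var_frac = pca(scaled, min(n_pcs, *scaled.shape))
    return select_top_transcripts(loadings, var_frac, kept, fraction, n_pcs)


def write_selection(sel: PCASelection, path) -> None:
    """Serialize as TSV: one row per (gene, component) with squared loading."""
    rows = []
    selected = set(sel.selected_gene_ids)
    for c in range(sel.loadings.shape[1]):
        in_pc = set(sel.per_pc_selected.get(c, []))
        for i, g in enumerate(sel.gene_ids):
            rows.append(
                {
                    "gene_id": g,
                    "pc": c + 1,
                    "squared_loading": sel.loadings[i, c] ** 2,
                    "selected_in_pc": int(g in in_pc),
                    "selected": int(g in selected),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
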