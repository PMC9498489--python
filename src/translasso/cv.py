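"""Contrast construction, cross-validated lambda path and stability scoring.

For every case/control contrast the workflow is: build binary labels,
assign stratified folds, and for each fold fit the box-constrained lasso
along the whole lambda grid on the training samples only (standardization
estimated on training data; held-out samples projected onto that scale).
Held-out AUC is recorded per (fold, lambda).  The penalty is then chosen by
the median-AUC rule: per lambda, the median of the fold AUCs above the null
cutoff (0.5) is computed, and the largest lambda whose median is within a
small tolerance of the best is selected — trading a little precision for
stronger shrinkage, analogous to the one-standard-error convention.

Stability is scored by occurrence counts: the number of (fold, lambda)
models in which a transcript carries a nonzero coefficient, with a ceiling
of n_folds x |lambda grid| (400 under the defaults).  The final model is a
refit on all contrast samples at the selected lambda; its reported AUC is
the cross-validated median over folds, with a percentile confidence
interval across folds (a DeLong interval on the full-data refit is reported
alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import (
    PipelineConfig,
    SampleTable,
    TranslassoError,
    ValidationError,
    stage,
    write_json,
)
from .lasso import (
    LassoFit,
    fit_lambda_path,
    make_design,
    predict_proba,
    project_design,
)
from .pca import PCASelection, preselect
from .preprocess import NormalizedMatrix

__all__ = [
    "Contrast",
    "CVRecord",
    "CVGrid",
    "CVReport",
    "CONTRAST_NAMES",
    "build_contrast",
    "assign_folds",
    "auc",
    "auc_ci_delong",
    "run_cv_grid",
    "select_lambda",
    "occurrence_counts",
    "finalize",
    "run_contrast",
    "write_report",
]


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """A named binary classification problem over the sample table."""

    name: str
    case_filter: Callable[[SampleTable], np.ndarray]
    control_filter: Callable[[SampleTable], np.ndarray]


def _diag_mask(t: SampleTable, diag: str) -> np.ndarray:
    if diag == "IBD":
        return t.is_case
    return t.diagnosis == diag


def _age_mask(t: SampleTable, age: str | None) -> np.ndarray:
    if age is None:
        return np.ones(len(t), dtype=bool)
    return t.age_group == age


def _active_mask(t: SampleTable, grade2_active: bool) -> np.ndarray:
    return t.activity >= (2 if grade2_active else 3)


def _remission_mask(t: SampleTable, grade2_remission: bool) -> np.ndarray:
    return t.activity <= (2 if grade2_remission else 1)


def _builtin_contrasts(config: PipelineConfig) -> dict[str, Contrast]:
    out: dict[str, Contrast] = {}
    for diag in ("IBD", "UC", "CD"):
        for age, suffix in ((None, ""), ("adult", "_adults"), ("child", "_children")):
            name = f"{diag}_vs_control{suffix}"

            def case_f(t, diag=diag, age=age):
                return _diag_mask(t, diag) & _age_mask(t, age)

            def ctrl_f(t, age=age):
                return (t.diagnosis == "control") & _age_mask(t, age)

            out[name] = Contrast(name, case_f, ctrl_f)
    g2a = config.grade2_policy == "active"
    g2r = config.grade2_policy == "remission"
    for diag in ("IBD", "UC", "CD"):
        name = f"active_{diag}"

        def case_f(t, diag=diag):
            return _diag_mask(t, diag) & _active_mask(t, g2a)

        def ctrl_f(t, diag=diag):
            # grouped controls plus patients of this diagnosis in remission
            return (t.diagnosis == "control") | (
                _diag_mask(t, diag) & _remission_mask(t, g2r)
            )

        out[name] = Contrast(name, case_f, ctrl_f)
    return out


CONTRAST_NAMES = tuple(_builtin_contrasts(PipelineConfig()).keys())


def build_contrast(
    samples: SampleTable,
    name: str,
    config: PipelineConfig | None = None,
) -> tuple[Contrast, np.ndarray, np.ndarray]:
    """Resolve a built-in contrast to ``(contrast, sample mask, labels)``.

    ``mask`` marks the samples entering the analysis; ``labels`` (over the
    masked samples, in sample order) are 1 for cases and 0 for the control
    class.  Samples matching neither filter are excluded.
    """
    config = config or PipelineConfig()
    builtins = _builtin_contrasts(config)
    if name not in builtins:
        raise ValidationError(
            f"unknown contrast {name!r}; available: {sorted(builtins)}"
        )
    contrast = builtins[name]
    case = contrast.case_filter(samples)
    ctrl = contrast.control_filter(samples) & ~case
    if not case.any():
        raise TranslassoError(f"contrast {name!r} has no case samples")
    if not ctrl.any():
        raise TranslassoError(f"contrast {name!r} has no control-class samples")
    mask = case | ctrl
    labels = case[mask].astype(np.int64)
    return contrast, mask, labels


# ---------------------------------------------------------------------------
# Folds and AUC
# ---------------------------------------------------------------------------


def assign_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment, deterministic given the seed.

    Within each class the samples are shuffled and dealt round-robin, so
    per-fold class counts differ by at most one from perfect proportion.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise TranslassoError(
                f"class {cls} has {len(idx)} samples < {n_folds} folds; "
                "reduce n_folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random case outscores random control), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci_delong(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.90
) -> tuple[float, float, float]:
    """DeLong variance-based AUC confidence interval.

    Returns ``(auc, lower, upper)`` using the structural-component
    (midrank) estimator of the AUC variance and a normal interval clipped
    to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    x = scores[labels == 1]  # cases
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValidationError("AUC requires both classes")
    all_ranks = rankdata(np.concatenate([x, y]))
    rx = rankdata(x)
    ry = rankdata(y)
    v10 = (all_ranks[:m] - rx) / n  # per-case structural components
    v01 = 1.0 - (all_ranks[m:] - ry) / m  # per-control
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    zq = norm.ppf(0.5 + level / 2)
    return a, max(0.0, a - zq * se), min(1.0, a + zq * se)


# ---------------------------------------------------------------------------
# Cross-validated lambda grid
# ---------------------------------------------------------------------------


@dataclass
class CVRecord:
    """One (fold, lambda) model: held-out AUC and the active transcripts."""

    fold: int
    lam: float
    auc: float
    active_genes: list[str]
    converged: bool
    beta: np.ndarray
    intercept: float


@dataclass
class CVGrid:
    """All (fold, lambda) records plus the fold assignment."""

    records: list[CVRecord]
    folds: np.ndarray
    lambda_grid: tuple[float, ...]
    n_folds: int
    feature_ids_per_fold: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class CVReport:
    """Final per-contrast report in the shape of the published model tables."""

    contrast: str
    median_auc_per_lambda: dict[float, float]
    selected_lambda: float
    occurrence: dict[str, int]
    final_fit: LassoFit
    final_auc: float
    ci_lower: float
    ci_upper: float
    delong: tuple[float, float, float]
    fold_aucs_at_selected: list[float]
    model_table: pd.DataFrame  # columns: gene, coefficient, occurrence_n


def run_cv_grid(
    nm: NormalizedMatrix,
    selection: PCASelection,
    labels: np.ndarray,
    config: PipelineConfig,
    folds: np.ndarray | None = None,
) -> CVGrid:
    """Fit the full folds x lambda grid with training-only standardization.

    ``nm`` must already be restricted to the contrast samples, in the order
    of ``labels``.  Each fold's held-out samples take no part in
    standardization, fitting, or (when ``nested_preselection`` is on)
    preselection.  Non-converged fits are recorded with their flag; they
    are excluded from lambda selection downstream but still counted for
    occurrences.
    """
    labels = np.asarray(labels)
    if folds is None:
        folds = assign_folds(labels, config.n_folds, config.rng_seed)
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    records: list[CVRecord] = []
    feature_ids_per_fold: dict[int, list[str]] = {}
    for fold in range(config.n_folds):
        test = folds == fold
        train = ~test
        if config.nested_preselection:
            sel = preselect(
                NormalizedMatrix(
                    list(nm.gene_ids),
                    [s for s, m in zip(nm.sample_ids, train) if m],
                    nm.values[:, train],
                    nm.size_factors[train],
                ),
                config.n_pcs,
                config.pc_variance_fraction,
            )
            feat = sel.selected_gene_ids
        else:
            feat = selection.selected_gene_ids
        rows = [gene_index[g] for g in feat]
        F = nm.values[rows, :].T  # samples x features
        d = make_design(F[train], labels[train], feature_ids=feat)
        X_test = project_design(d, F[test])
        fits = fit_lambda_path(
            d, config.lambda_grid, config.coef_lower, config.coef_upper
        )
        feature_ids_per_fold[fold] = list(feat)
        y_test = labels[test]
        for lam, fit in zip(config.lambda_grid, fits):
            p_test = predict_proba(fit, X_test)
            fold_auc = auc(p_test, y_test)
            active = [feat[j] for j in fit.active_set]
            records.append(
                CVRecord(
                    fold=fold,
                    lam=lam,
                    auc=fold_auc,
                    active_genes=active,
                    converged=fit.converged,
                    beta=fit.beta.copy(),
                    intercept=fit.intercept,
                )
            )
    return CVGrid(
        records=records,
        folds=folds,
        lambda_grid=tuple(config.lambda_grid),
        n_folds=config.n_folds,
        feature_ids_per_fold=feature_ids_per_fold,
    )


def median_auc_table(grid: CVGrid, config: PipelineConfig) -> dict[float, float]:
    """Per-lambda median of the converged fold AUCs above the null cutoff.

    A lambda with no qualifying fold is absent from the table (ineligible).
    """
    table: dict[float, float] = {}
    for lam in grid.lambda_grid:
        qual = [
            r.auc
            for r in grid.records
            if r.lam == lam and r.converged and r.auc > config.auc_null_cutoff
        ]
        if qual:
            table[lam] = float(np.median(qual))
    return table


def select_lambda(
    grid: CVGrid, config: PipelineConfig
) -> tuple[float, dict[float, float]]:
    """Largest eligible lambda whose median AUC is within tolerance of the best."""
    table = median_auc_table(grid, config)
    if not table:
        summary = {
            lam: float(
                np.median([r.auc for r in grid.records if r.lam == lam])
            )
            for lam in grid.lambda_grid
        }
        raise TranslassoError(
            "no lambda has any fold with AUC above the null cutoff "
            f"{config.auc_null_cutoff}; per-lambda median AUCs: {summary}"
        )
    best = max(table.values())
    eligible = [
        lam for lam, med in table.items() if med >= best - config.lambda_tolerance
    ]
    return max(eligible), table


def occurrence_counts(grid: CVGrid) -> dict[str, int]:
    """Times each transcript is active across all (fold, lambda) models.

    Counts include non-converged fits; the ceiling is
    ``n_folds * |lambda_grid|``.  Transcripts never active are absent
    (implicitly zero).
    """
    counts: dict[str, int] = {}
    for r in grid.records:
        for g in r.active_genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def finalize(
    nm: NormalizedMatrix,
    selection: PCASelection,
    labels: np.ndarray,
    selected_lambda: float,
    grid: CVGrid,
    config: PipelineConfig,
    contrast_name: str = "",
) -> CVReport:
    """Refit on all contrast samples at the selected lambda and report.

    The model table lists active transcripts with coefficients sorted
    descending (positive at the top, negative at the bottom) and their
    occurrence counts.  The reported AUC is the median of the held-out fold
    AUCs at the selected lambda; the confidence interval is the empirical
    percentile interval of those fold AUCs at the configured level.
    """
    labels = np.asarray(labels)
    feat = selection.selected_gene_ids
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    rows = [gene_index[g] for g in feat]
    F = nm.values[rows, :].T
    d = make_design(F, labels, feature_ids=feat)
    # warm-started path down to the selected lambda, matching the CV fits
    path_lams = tuple(l for l in config.lambda_grid if l >= selected_lambda)
    fits = fit_lambda_path(d, path_lams, config.coef_lower, config.coef_upper)
    final_fit = fits[0]  # smallest lambda of the truncated path = selected
    occurrence = occurrence_counts(grid)
    active = final_fit.active_set
    table = pd.DataFrame(
        {
            "gene": [feat[j] for j in active],
            "coefficient": [float(final_fit.beta[j]) for j in active],
            "occurrence_n": [occurrence.get(feat[j], 0) for j in active],
        }
    )
    table = table.sort_values(
        "coefficient", ascending=False, kind="stable"
    ).reset_index(drop=True)
    fold_aucs = [r.auc for r in grid.records if r.lam == selected_lambda]
    point = float(np.median(fold_aucs))
    alpha = (1 - config.ci_level) / 2
    lo, hi = np.percentile(fold_aucs, [100 * alpha, 100 * (1 - alpha)])
    resub = predict_proba(final_fit, d.X)
    delong = auc_ci_delong(resub, labels, config.ci_level)
    medians = median_auc_table(grid, config)
    return CVReport(
        contrast=contrast_name,
        median_auc_per_lambda=medians,
        selected_lambda=float(selected_lambda),
        occurrence=occurrence,
        final_fit=final_fit,
        final_auc=point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        delong=delong,
        fold_aucs_at_selected=[float(a) for a in fold_aucs],
        model_table=table,
    )


# ---------------------------------------------------------------------------
# Per-contrast orchestration and reporting
# ---------------------------------------------------------------------------


def run_contrast(
    nm: NormalizedMatrix,
    samples: SampleTable,
    name: str,
    config: PipelineConfig,
) -> CVReport:
    """Run preselection + cross-validated lasso for one named contrast.

    ``nm`` is the full normalized matrix over all samples; the contrast's
    sample subset is taken here.  Preselection runs once on the contrast
    subset (cases plus controls by default, cases only if
    ``pca_include_controls`` is off) before cross-validation; the
    ``nested_preselection`` flag instead recomputes it inside each training
    fold for leakage-free evaluation.
    """
    _, mask, labels = build_contrast(samples, name, config)
    sub = NormalizedMatrix(
        list(nm.gene_ids),
        [s for s, m in zip(nm.sample_ids, mask) if m],
        nm.values[:, mask],
        nm.size_factors[mask],
    )
    pca_mask = None if config.pca_include_controls else labels == 1
    with stage("preselect", contrast=name, genes=len(sub.gene_ids)):
        selection = preselect(
            sub, config.n_pcs, config.pc_variance_fraction, sample_mask=pca_mask
        )
    with stage(
        "cv_grid",
        contrast=name,
        features=len(selection.selected_gene_ids),
        folds=config.n_folds,
        lambdas=len(config.lambda_grid),
    ):
        grid = run_cv_grid(sub, selection, labels, config)
    selected, _ = select_lambda(grid, config)
    with stage("finalize", contrast=name, selected_lambda=selected):
        report = finalize(
            sub, selection, labels, selected, grid, config, contrast_name=name
        )
    return report


def write_report(report: CVReport, grid: CVGrid, outdir: str | Path) -> None:
    """Write ``model.tsv``, ``cv.tsv`` and ``summary.json`` deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.model_table.to_csv(
        outdir / "model.tsv", sep="\t", index=False, float_format="%.10g"
    )
    cv_rows = pd.DataFrame(
        {
            "fold": [r.fold for r in grid.records],
            "lambda": [r.lam for r in grid.records],
            "auc": [r.auc for r in grid.records],
            "active_set_size": [len(r.active_genes) for r in grid.records],
            "converged": [int(r.converged) for r in grid.records],
        }
    )
    cv_rows.to_csv(outdir / "cv.tsv", sep="\t", index=False, float_format="%.10g")
    summary = {
        "contrast": report.contrast,
        "selected_lambda": report.selected_lambda,
        "auc": report.final_auc,
        "ci_level_percentile": [report.ci_lower, report.ci_upper],
        "delong_resubstitution": list(report.delong),
        "intercept": report.final_fit.intercept,
        "n_active": int(len(report.model_table)),
        "fold_aucs_at_selected": report.fold_aucs_at_selected,
    }
    write_json(summary, outdir / "summary.json")
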