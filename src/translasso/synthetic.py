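"""Negative-binomial count simulator for case/control blood transcriptomes.

Generates gene x sample count matrices with the statistical structure the
downstream analysis assumes: overdispersed counts, per-sample library-size
variation, a planted subset of case-differential (signal) genes, and
correlated co-expression blocks driven by shared latent factors — the
small-scale co-expression clusters that the PCA preselection stage is meant
to summarize.

Model
-----
For gene *i* and sample *j* the expected count is

    mu_ij = s_j * 2 ** (m_i + delta_i * case_j + b_ij)

where ``s_j`` is a log-normal size factor, ``m_i`` a uniform per-gene log2
baseline, ``delta_i`` the planted log2 fold change (nonzero only for signal
genes, applied to cases) and ``b_ij = sqrt(rho) * f_{block(i), j}`` a shared
standard-normal latent block factor.  Counts are drawn negative-binomially
with variance ``mu + phi * mu**2`` (gamma-Poisson mixture with shape
``1/phi``).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable, ValidationError

__all__ = ["SimulationSpec", "simulate_dataset", "split_activity", "write_truth", "read_truth"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a moderately overdispersed (phi = 0.2) whole-blood-like
    cohort of 100 cases and 100 controls over 2,000 genes, with 20 signal
    genes at log2 fold change 1.5, five co-expression blocks of 20 genes,
    ~20% library-size spread, and half of the cases in an active flare.
    """

    n_genes: int = 2000
    n_cases: int = 100
    n_controls: int = 100
    n_signal_genes: int = 20
    log2_fold_change: float = 1.5
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    nb_dispersion: float = 0.2
    size_factor_log_sd: float = 0.2
    n_blocks: int = 5
    block_size: int = 20
    block_rho: float = 0.3
    activity_fraction: float = 0.5
    signal_in_blocks: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_controls < 1 or self.n_cases < 0:
            raise ValidationError("cohort dimensions must be positive")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ValidationError("n_signal_genes must lie in [0, n_genes]")
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValidationError("n_blocks * block_size exceeds n_genes")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValidationError("baseline_log2_mean_range must be ordered")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.size_factor_log_sd < 0:
            raise ValidationError("size_factor_log_sd must be >= 0")
        if not 0 <= self.block_rho < 1:
            raise ValidationError("block_rho must lie in [0, 1)")
        if not 0 <= self.activity_fraction <= 1:
            raise ValidationError("activity_fraction must lie in [0, 1]")


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[CountMatrix, SampleTable, list[str]]:
    """Draw a (counts, samples, truth) triple from ``spec``.

    Cases come first in sample order and are labelled UC / CD alternately;
    age groups alternate adult / child.  The returned truth list contains
    the ids of the planted signal genes.
    """
    rng = np.random.default_rng(spec.seed)
    G, n1, n0 = spec.n_genes, spec.n_cases, spec.n_controls
    n = n1 + n0
    width = max(4, len(str(G)))
    gene_ids = [f"G{idx:0{width}d}" for idx in range(1, G + 1)]
    sample_ids = [f"S{idx:03d}" for idx in range(1, n + 1)]
    case = np.zeros(n)
    case[:n1] = 1.0

    # gene block membership: blocks occupy the leading genes
    block_of = np.full(G, -1, dtype=np.int64)
    for b in range(spec.n_blocks):
        block_of[b * spec.block_size : (b + 1) * spec.block_size] = b
    in_block = block_of >= 0

    # planted signal genes, disjoint from blocks unless requested otherwise
    eligible = np.flatnonzero(in_block if spec.signal_in_blocks else ~in_block)
    if len(eligible) < spec.n_signal_genes:
        raise ValidationError("not enough eligible genes to plant the signal")
    signal_idx = np.sort(rng.choice(eligible, size=spec.n_signal_genes, replace=False))
    delta = np.zeros(G)
    delta[signal_idx] = spec.log2_fold_change

    lo, hi = spec.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=G)
    size_factors = np.exp(rng.normal(0.0, spec.size_factor_log_sd, size=n))

    log2_mu = baseline[:, None] + delta[:, None] * case[None, :]
    if spec.n_blocks > 0 and spec.block_rho > 0:
        latent = rng.standard_normal((spec.n_blocks, n))
        block_effect = np.sqrt(spec.block_rho) * latent[block_of[in_block], :]
        log2_mu[in_block, :] += block_effect
    mu = size_factors[None, :] * np.exp2(log2_mu)

    phi = spec.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64))

    diagnosis = np.array(
        ["UC" if k % 2 == 0 else "CD" for k in range(n1)] + ["control"] * n0,
        dtype=object,
    )
    age_group = np.array(
        ["adult" if k % 2 == 0 else "child" for k in range(n)], dtype=object
    )
    table = SampleTable(sample_ids, diagnosis, age_group, np.zeros(n, dtype=np.int64))
    table = split_activity(table, spec.activity_fraction, seed=spec.seed + 1)

    truth = [gene_ids[i] for i in signal_idx]
    return cm, table, truth


def split_activity(table: SampleTable, fraction: float, seed: int) -> SampleTable:
    """Assign activity grades: ``fraction`` of cases become active (3-4).

    Exactly ``round(fraction * n_cases)`` cases, chosen uniformly at random,
    receive grade 3 or 4; the remaining cases receive grade 0-2; controls
    stay at 0.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(table.is_case)
    n_active = int(round(fraction * len(case_idx)))
    active_idx = rng.choice(case_idx, size=n_active, replace=False)
    activity = np.zeros(len(table), dtype=np.int64)
    activity[case_idx] = rng.integers(0, 3, size=len(case_idx))
    activity[active_idx] = rng.integers(3, 5, size=n_active)
    return SampleTable(
        list(table.sample_ids),
        table.diagnosis.copy(),
        table.age_group.copy(),
        activity,
    )


def write_truth(truth: list[str], path) -> None:
    pd.DataFrame({"gene_id": truth}).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[str]:
    return [str(g) for g in pd.read_csv(path, sep="\t")["gene_id"]]
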