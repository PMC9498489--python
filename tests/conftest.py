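import numpy as np
import pytest
from scipy.special import expit

import translasso as tl


def proximal_gradient_oracle(X, y, lam, lower, upper, iters=10_000):
    """Independent solver for the box-constrained L1 logistic objective.

    Accelerated proximal gradient (FISTA) with an exact Lipschitz step; the
    prox of the L1 term plus box indicator is soft-thresholding followed by
    clipping.  Deliberately shares no code with the coordinate-descent
    implementation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    L = np.linalg.eigvalsh(Xa.T @ Xa / n).max() / 4
    t = 1.0 / L

    def prox_step(b):
        g = Xa.T @ (expit(Xa @ b) - y) / n
        v = b - t * g
        z = np.sign(v[1:]) * np.maximum(np.abs(v[1:]) - t * lam, 0.0)
        return np.concatenate([[v[0]], np.clip(z, lower, upper)])

    b = np.zeros(p + 1)
    momentum = b.copy()
    s = 1.0
    for _ in range(iters):
        b_new = prox_step(momentum)
        s_new = (1.0 + np.sqrt(1.0 + 4.0 * s * s)) / 2.0
        momentum = b_new + ((s - 1.0) / s_new) * (b_new - b)
        b, s = b_new, s_new
    b = prox_step(b)  # final plain step keeps the iterate feasible/stable
    return b[0], b[1:]


def brute_force_auc(scores, labels):
    """O(n^2) pairwise Mann-Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for u in ctrls:
            if c > u:
                total += 1.0
            elif c == u:
                total += 0.5
    return total / (len(cases) * len(ctrls))


def random_logistic_instance(rng, n_max=50, p_max=3):
    """A small random standardized design with Bernoulli labels (both classes)."""
    while True:
        n = int(rng.integers(10, n_max + 1))
        p = int(rng.integers(1, p_max + 1))
        X = rng.standard_normal((n, p))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        coef = rng.uniform(-1, 1, size=p)
        y = (rng.random(n) < expit(X @ coef + rng.normal(0, 0.5))).astype(float)
        if 0 < y.mean() < 1:
            return X, y


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared across orchestration tests."""
    spec = tl.SimulationSpec(
        n_genes=300, n_cases=40, n_controls=40, n_signal_genes=10, seed=11
    )
    cm, table, truth = tl.simulate_dataset(spec)
    nm = tl.preprocess_counts(cm, 10)
    return cm, table, truth, nm
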