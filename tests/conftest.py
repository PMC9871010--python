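import numpy as np
import pytest

from celltwas import (
    PriorScoreVector,
    SignatureExpressionMatrix,
    TrainingGeneData,
)


@pytest.fixture(scope="session")
def heterogeneous_training():
    """Bulk mixture with distinct causal SNPs in the two cell types.

    SNP 7 drives expression in the cell type of interest, SNP 13 in the
    other cells, each with effect 1 and a mean offset of 1, matching the
    heterogeneous SNP-expression design of the power studies.
    """
    rng = np.random.default_rng(777)  # causal-SNP MAFs ~0.3: heritability near the design median
    n, p = 300, 50
    X = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
    pi = np.clip(rng.beta(2, 3, n), 1e-3, 1 - 1e-3)
    u = 1.0 + X[:, 7] + rng.standard_normal(n)
    v = X[:, 13] + rng.standard_normal(n)
    y = pi * u + (1 - pi) * v
    return TrainingGeneData(y=y, X=X, pi_hat=pi), {"p1": 7, "p2": 13, "pi": pi}


@pytest.fixture(scope="session")
def signature_fixture():
    """Signature-gene mixture with informative genes and a noisy prior.

    50 genes with a mean shift of 2 between cell types (unit SDs), true
    proportions Beta(2,3), and a prior drawn Beta(5.5*pi, 5.5*(1-pi)) so
    that its correlation with the truth is roughly 0.6.
    """
    rng = np.random.default_rng(42)
    N, G = 200, 50
    pi = np.clip(rng.beta(2, 3, N), 0.01, 0.99)
    mu_T = rng.normal(0, 1, G)
    mu_S = mu_T + 2.0
    S = rng.normal(mu_S, 1.0, (N, G))
    T = rng.normal(mu_T, 1.0, (N, G))
    W = pi[:, None] * S + (1 - pi[:, None]) * T
    h = np.clip(rng.beta(5.5 * pi, 5.5 * (1 - pi)), 1e-4, 1 - 1e-4)
    sig = SignatureExpressionMatrix(W=W, gene_ids=np.arange(G), sample_ids=np.arange(N))
    prior = PriorScoreVector(np.arange(N), h)
    return sig, prior, pi
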