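import numpy as np
import pytest

from ridgepred.io_formats import GenotypeMatrix
from ridgepred.preprocess import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n, p, missing_frac=0.0):
    """A GenotypeMatrix of iid binomial counts (optionally with missing calls)."""
    f = rng.uniform(0.1, 0.9, size=p)
    counts = rng.binomial(2, f, size=(n, p)).astype(np.int8)
    if missing_frac:
        mask = rng.random((n, p)) < missing_frac
        counts[mask] = -1
    return GenotypeMatrix(counts,
                          [f"ind{i}" for i in range(n)],
                          [f"snp{j}" for j in range(p)],
                          allele_freqs=f)


def standardized_pair(rng, n, n2, p):
    """Training/test standardized dosages sharing the training scaling."""
    gm = random_genotypes(rng, n + n2, p)
    train = GenotypeMatrix(gm.counts[:n], gm.sample_ids[:n], gm.snp_ids)
    test = GenotypeMatrix(gm.counts[n:], gm.sample_ids[n:], gm.snp_ids)
    std = standardize(train)
    return std.X, std.transform(test)


@pytest.fixture(scope="session")
def smoke_study():
    """The scaled-down ridge-vs-GWAS study: N = P = 2,000, 21 runs.

    Session-scoped because the 21 eigendecompositions dominate the suite's
    runtime; every consumer treats the result as read-only.
    """
    from ridgepred.simstudy import compute_metrics, run_study, select_lambda_median
    from ridgepred.simulate import SimConfig

    table = run_study(SimConfig.smoke(seed=2026))
    records = compute_metrics(select_lambda_median(table))
    return table, records
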