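import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pool():
    from rareburden.simulate import simulate_haplotype_pool
    return simulate_haplotype_pool(2000, 10_000, sfs_shape=1.0, seed=11)


@pytest.fixture(scope="session")
def signal_fixture():
    """100-sample, 5-variant genotype/phenotype fixture with a real but
    moderate association, for oracle comparisons."""
    rng = np.random.default_rng(42)
    n = 100
    G = rng.binomial(2, [0.05, 0.08, 0.1, 0.04, 0.06], size=(n, 5)).astype(float)
    # mixed-direction effects so burden, SKAT and SKAT-O all land at
    # moderate p-values where oracle comparisons are informative
    score = G @ np.array([1.8, -1.5, 1.0, 0.5, 0.0])
    p = 1 / (1 + np.exp(-(-0.5 + score)))
    y = (rng.random(n) < p).astype(float)
    if y.min() == y.max():  # pragma: no cover
        y[0] = 1 - y[0]
    return y, G


@pytest.fixture(scope="session")
def qc_bundle():
    """QC metrics + IBD with a known planted-outlier truth table."""
    from rareburden.simulate import OutlierSpec, simulate_qc_metrics
    ids = [f"S{i:03d}" for i in range(120)]
    spec = OutlierSpec(n_contaminated=4, n_low_depth=3, n_discordant=2,
                       n_high_missing=2, n_non_european=3,
                       n_reported_non_european=1, related_groups=(2, 3))
    qc, ibd, truth = simulate_qc_metrics(ids, spec, seed=7)
    groups = np.where(np.arange(len(qc)) % 3 == 0, "diseased_control", "case")
    qc = qc.assign(group=groups)
    return qc, ibd, truth


@pytest.fixture(scope="session")
def classified_fixture():
    """Classified variant table from a coherent synthetic bundle."""
    from rareburden.classify import classify_variants
    from rareburden.io import generate_dataset
    bundle = generate_dataset(seed=23, n_genes=6, n_cases_ts=60,
                              n_cases_wes=30, n_controls=60,
                              n_haplotypes=1000, region_per_gene=2500)
    classified = classify_variants(bundle["annotations"], bundle["panels"])
    classified["g_index"] = np.arange(len(classified))
    return bundle, classified
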