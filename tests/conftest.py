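import numpy as np
import pytest

from covgeno import RegionSpec, SimulationConfig, build_toy_locus, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A 30-sample single-region cohort with the default cross-mapped exon."""
    return SimulationConfig(
        regions={"r": RegionSpec(30, (1 / 3, 1 / 3, 1 / 3))}, seed=11
    )


@pytest.fixture(scope="session")
def clean_config():
    """As small_config but without cross-mapping (no artifact structure)."""
    return SimulationConfig(
        regions={"r": RegionSpec(30, (1 / 3, 1 / 3, 1 / 3))}, cross_map=(), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    reads, truth = simulate_cohort(small_config)
    features, _ = build_toy_locus(small_config)
    return reads, truth, features


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    reads, truth = simulate_cohort(clean_config)
    features, _ = build_toy_locus(clean_config)
    return reads, truth, features


def random_read_fixture(rng, n_reads=200, n_exons=5, chrom="chr1", sample="S1"):
    """Random reads and exons on a 1 kb window, for oracle comparisons."""
    from covgeno import GeneFeature, ReadRecord

    reads = [
        ReadRecord(
            sample_id=sample,
            chrom=chrom,
            start=int(rng.integers(0, 900)),
            length=int(rng.integers(1, 120)),
            mapq=int(rng.integers(0, 61)),
            is_duplicate=bool(rng.random() < 0.1),
            is_multimapped=bool(rng.random() < 0.2),
        )
        for _ in range(int(rng.integers(1, n_reads + 1)))
    ]
    k = int(rng.integers(1, n_exons + 1))
    bounds = np.sort(rng.choice(np.arange(0, 1000), size=2 * k, replace=False))
    exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(k))
    feature = GeneFeature(
        feature_id="F", family="fam", chrom=chrom, strand="+", exons=exons
    )
    return reads, feature
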