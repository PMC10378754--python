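import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rohscape.genotypes import GenotypeMatrix, HET, HOM_A, HOM_B, MISSING, MarkerMap

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_map(chrom_snp_counts: dict[str, int], spacing_bp: int = 40_000) -> MarkerMap:
    """Evenly spaced markers per chromosome."""
    records = []
    for chrom, m in chrom_snp_counts.items():
        for j in range(m):
            records.append((chrom, f"c{chrom}_s{j}", (j + 1) * spacing_bp))
    return MarkerMap.from_records(records)


def random_codes(
    rng: np.random.Generator,
    n: int,
    m: int,
    p_het: float = 0.08,
    p_missing: float = 0.03,
) -> np.ndarray:
    u = rng.random((n, m))
    hom_split = p_het + p_missing + (1 - p_het - p_missing) / 2
    return np.select(
        [u < p_het, u < p_het + p_missing, u < hom_split],
        [HET, MISSING, HOM_A],
        default=HOM_B,
    ).astype(np.int8)


def random_matrix(
    rng: np.random.Generator, n: int, m: int, n_chrom: int = 1, **kwargs
) -> GenotypeMatrix:
    per = m // n_chrom
    markers = make_map({str(c + 1): per for c in range(n_chrom)})
    codes = random_codes(rng, n, per * n_chrom, **kwargs)
    return GenotypeMatrix([f"s{i}" for i in range(n)], codes, markers)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230715)
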