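"""Minor-allele-frequency spectra and the exact Hardy–Weinberg test.

The HWE test is the exact conditional test: given the observed allele
counts, the number of heterozygotes follows a known distribution under
random mating, and the two-sided p-value sums the probabilities of all
heterozygote counts no more probable than the observed one.  Homozygote
excess is declared when observed heterozygotes fall below the classical
2pqn expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix, HET, HOM_A, HOM_B

__all__ = [
    "maf",
    "MafSpectrum",
    "maf_spectrum",
    "ExcessDirection",
    "HweResult",
    "hwe_exact",
    "hwe_summary",
    "DEFAULT_MAF_BIN_EDGES",
]

#: (0, 0.1], (0.1, 0.2], ... (0.4, 0.5]; MAF == 0 is its own (monomorphic) class.
DEFAULT_MAF_BIN_EDGES: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def maf(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Minor allele frequency from genotype counts (missing excluded).

    Returns NaN for an all-missing marker (undefined MAF).
    """
    n = n_AA + n_AB + n_BB
    if n == 0:
        return float("nan")
    p = (2 * n_AA + n_AB) / (2 * n)
    return min(p, 1.0 - p)


@dataclass
class MafSpectrum:
    """Per-marker MAF values with binned counts and % polymorphic."""

    maf: np.ndarray
    bin_edges: tuple[float, ...]
    n_monomorphic: int
    bin_counts: np.ndarray
    percent_polymorphic: float
    n_defined: int

    def to_frame(self) -> pd.DataFrame:
        labels = ["MAF = 0"] + [
            f"({lo:g}, {hi:g}]"
            for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
        ]
        counts = [self.n_monomorphic, *self.bin_counts.tolist()]
        return pd.DataFrame({"maf_bin": labels, "n_snps": counts})


def maf_spectrum(
    gm: GenotypeMatrix, bin_edges: tuple[float, ...] = DEFAULT_MAF_BIN_EDGES
) -> MafSpectrum:
    """Per-marker MAF (non-missing calls only) and its binned distribution.

    percent_polymorphic = 100 · #(MAF > 0) / #(markers with defined MAF).
    """
    n_AA = (gm.codes == HOM_A).sum(axis=0)
    n_AB = (gm.codes == HET).sum(axis=0)
    n_BB = (gm.codes == HOM_B).sum(axis=0)
    n = n_AA + n_AB + n_BB
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_AA + n_AB) / (2 * n)
    values = np.where(n > 0, np.minimum(p, 1 - p), np.nan)
    defined = values[~np.isnan(values)]
    n_mono = int((defined == 0).sum())
    poly = defined[defined > 0]
    counts, _ = np.histogram(poly, bins=np.asarray(bin_edges))
    pct = 100.0 * len(poly) / len(defined) if len(defined) else float("nan")
    return MafSpectrum(
        maf=values,
        bin_edges=tuple(bin_edges),
        n_monomorphic=n_mono,
        bin_counts=counts,
        percent_polymorphic=pct,
        n_defined=len(defined),
    )


class ExcessDirection(Enum):
    HOM_EXCESS = "HOM_EXCESS"
    HET_EXCESS = "HET_EXCESS"
    NONE = "NONE"


@dataclass
class HweResult:
    n_AA: int
    n_AB: int
    n_BB: int
    p_value: float
    expected_het: float
    direction: ExcessDirection


@lru_cache(maxsize=4096)
def _het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given allele counts.

    ``n`` diploid individuals carry ``n_a`` copies of allele A (and
    ``2n - n_a`` of allele B).  Admissible heterozygote counts share the
    parity of ``n_a`` and run from ``n_a mod 2`` (or the forced minimum when
    A-alleles outnumber 2·possible homozygote slots) to ``min(n_a, 2n-n_a)``.

    Returns (het_counts, probabilities); probabilities sum to 1.
    """
    n_b = 2 * n - n_a
    hi = min(n_a, n_b)
    lo = n_a % 2
    hets = np.arange(lo, hi + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    # P(n_AB | n, n_a) ∝ n! / (n_AA! n_AB! n_BB!) · 2^n_AB
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return hets, probs


def hwe_exact(n_AA: int, n_AB: int, n_BB: int) -> HweResult | None:
    """Two-sided exact Hardy–Weinberg test for one biallelic marker.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities not exceeding that of the observed
    configuration.  Returns ``None`` for a monomorphic marker (the test is
    not applicable).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    if n == 0 or n_a == 0 or n_b == 0:
        return None
    hets, probs = _het_distribution(n, n_a)
    p_obs = probs[np.searchsorted(hets, n_AB)]
    p_value = float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    p_freq = n_a / (2 * n)
    expected_het = 2.0 * p_freq * (1.0 - p_freq) * n
    if n_AB < expected_het:
        direction = ExcessDirection.HOM_EXCESS
    elif n_AB > expected_het:
        direction = ExcessDirection.HET_EXCESS
    else:
        direction = ExcessDirection.NONE
    return HweResult(n_AA, n_AB, n_BB, p_value, expected_het, direction)


def hwe_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker HWE results for all polymorphic markers of a matrix."""
    counts = gm.genotype_counts()
    rows = []
    for snp_id, aa, ab, bb in zip(
        counts["snp_id"], counts["n_AA"], counts["n_AB"], counts["n_BB"]
    ):
        res = hwe_exact(int(aa), int(ab), int(bb))
        if res is None:
            continue
        rows.append(
            (snp_id, aa, ab, bb, res.p_value, res.expected_het, res.direction.value)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "n_AA",
            "n_AB",
            "n_BB",
            "p_value",
            "expected_het",
            "direction",
        ],
    )


def hwe_summary(gm: GenotypeMatrix, alpha: float = 0.05) -> tuple[float, float]:
    """Percent of polymorphic markers out of HWE, and, among those, the
    percent driven by homozygote excess.

    Expects an autosome-restricted matrix; monomorphic markers are skipped.
    Returns (NaN, NaN) when no marker is testable, and NaN for the second
    value when nothing is significant.
    """
    table = hwe_table(gm)
    if table.empty:
        return float("nan"), float("nan")
    sig = table[table["p_value"] < alpha]
    pct_diseq = 100.0 * len(sig) / len(table)
    if len(sig) == 0:
        return pct_diseq, float("nan")
    pct_hom = 100.0 * (sig["direction"] == "HOM_EXCESS").mean()
    return pct_diseq, pct_hom
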