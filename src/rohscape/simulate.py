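"""Synthetic genotype generators with known autozygosity ground truth.

Two generators are provided:

* a pedigree *gene-dropping* simulator — founder haplotypes are dropped
  through an arbitrary pedigree with Poisson crossovers (no interference,
  uniform positions on a linear genetic map), tracking identity-by-descent
  so that every truly autozygous interval is recorded as a truth segment;
* a direct *planted-segment* generator — homozygous intervals are written
  into a heterozygous background for a chosen fraction of carriers, giving
  exact ground truth for island-recovery tests.

Defaults emulate a ~60k-SNP porcine array on 18 autosomes totalling
2265.77 Mb, with a 1 Morgan genetic length per chromosome, 1% missingness
and a 0.2% heterozygote-error rate inside autozygous segments (the error
mode the ROH caller's one-heterozygote-per-window allowance exists for).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genotypes import (
    GenotypeMatrix,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    MarkerMap,
)

__all__ = [
    "SimConfig",
    "TruthSegment",
    "Pedigree",
    "FounderPool",
    "build_marker_map",
    "simulate_founders",
    "gene_drop",
    "plant_segments",
    "full_sib_pedigree",
    "sib_chain_pedigree",
    "simulate_pedigree",
    "simulate_island_groups",
    "save_config",
]

IBD_AUTOZYGOUS = "IBD_AUTOZYGOUS"
PLANTED_HOMOZYGOUS = "PLANTED_HOMOZYGOUS"


@dataclass(frozen=True)
class SimConfig:
    """Genome, pedigree-transmission and noise parameters for simulation.

    The defaults mirror a two-group SNP60-style study design: 18 autosomes
    of 125.88 Mb each (2265.77 Mb total), 3420 markers per chromosome
    (~61.6k genome-wide), founder minor-allele frequencies uniform on
    [0.05, 0.5].  ``seed`` is mandatory: every simulation is reproducible.
    """

    seed: int
    n_chromosomes: int = 18
    snps_per_chromosome: int = 3420
    chromosome_length_mb: float = 125.88
    chromosome_morgans: float = 1.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.01
    het_error_rate: float = 0.002
    marker_jitter: float = 0.0  # fraction of the mean spacing

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_error_rate", "maf_low", "maf_high"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one SNP")

    @property
    def chromosome_length_bp(self) -> int:
        return int(round(self.chromosome_length_mb * 1e6))


@dataclass(frozen=True)
class TruthSegment:
    """A simulator-planted/derived autozygous interval (recovery ground truth)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    kind: str = IBD_AUTOZYGOUS


class Pedigree:
    """Ordered pedigree: (individual, sire, dam), parents before offspring.

    Founders carry ``None`` parents.  The ordering requirement makes the
    pedigree acyclic by construction.
    """

    def __init__(self, entries: list[tuple[str, str | None, str | None]]):
        seen: set[str] = set()
        for ind, sire, dam in entries:
            if ind in seen:
                raise ValueError(f"duplicate pedigree entry {ind}")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"pedigree references unknown/later individual {parent!r} "
                        f"as a parent of {ind!r}"
                    )
            seen.add(ind)
        self.entries = list(entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def founders(self) -> list[str]:
        return [ind for ind, sire, dam in self.entries if sire is None and dam is None]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FounderPool:
    """Founder haplotypes: alleles[f, h, j] ∈ {0, 1} for founder f, haplotype h."""

    founder_ids: list[str]
    alleles: np.ndarray  # (n_founders, 2, M) uint8
    freqs: np.ndarray  # per-SNP frequency of allele 1 (the 'B' allele)

    @property
    def monomorphic(self) -> np.ndarray:
        """SNPs where the frequency is degenerate (0 or 1)."""
        return (self.freqs == 0.0) | (self.freqs == 1.0)


def build_marker_map(config: SimConfig, rng: np.random.Generator | None = None) -> MarkerMap:
    """Evenly spaced markers (optionally jittered) on every chromosome."""
    if config.marker_jitter > 0 and rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    m = config.snps_per_chromosome
    L = config.chromosome_length_bp
    spacing = L / m
    for c in range(1, config.n_chromosomes + 1):
        pos = spacing * (np.arange(m) + 0.5)
        if config.marker_jitter > 0:
            pos = pos + rng.uniform(-0.5, 0.5, m) * config.marker_jitter * spacing
        pos = np.maximum(np.round(pos).astype(np.int64), 1)
        pos = np.maximum.accumulate(pos)
        # enforce strictly increasing positions after rounding/jitter
        for j in range(1, m):
            if pos[j] <= pos[j - 1]:
                pos[j] = pos[j - 1] + 1
        records.extend(
            (str(c), f"chr{c}_snp{j}", int(pos[j])) for j in range(m)
        )
    return MarkerMap.from_records(records)


def simulate_founders(
    config: SimConfig,
    founder_ids: list[str],
    rng: np.random.Generator | None = None,
) -> FounderPool:
    """Draw 2 haplotypes per founder, each SNP independent at its frequency."""
    rng = rng or np.random.default_rng(config.seed)
    m_total = config.n_chromosomes * config.snps_per_chromosome
    freqs = rng.uniform(config.maf_low, config.maf_high, m_total)
    alleles = (rng.random((len(founder_ids), 2, m_total)) < freqs).astype(np.uint8)
    pool = FounderPool(list(founder_ids), alleles, freqs)
    if pool.monomorphic.any():
        warnings.warn(f"{int(pool.monomorphic.sum())} monomorphic founder SNPs")
    return pool


def _meiosis(
    alleles: np.ndarray,
    ancestry: np.ndarray,
    chrom_slices: list[slice],
    bp: np.ndarray,
    chrom_length_bp: int,
    morgans: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's two haplotypes: Poisson crossover count,
    uniform crossover positions, no interference."""
    m_total = bp.size
    gam_alleles = np.empty(m_total, dtype=np.uint8)
    gam_anc = np.empty(m_total, dtype=np.int32)
    for sl in chrom_slices:
        start_hap = int(rng.integers(2))
        n_x = int(rng.poisson(morgans))
        if n_x:
            xpos = np.sort(rng.uniform(0, chrom_length_bp, n_x))
            which = (start_hap + np.searchsorted(xpos, bp[sl])) % 2
        else:
            which = np.full(sl.stop - sl.start, start_hap)
        pick0 = which == 0
        gam_alleles[sl] = np.where(pick0, alleles[0, sl], alleles[1, sl])
        gam_anc[sl] = np.where(pick0, ancestry[0, sl], ancestry[1, sl])
    return gam_alleles, gam_anc


def _autozygous_truth(
    sample_id: str, auto_mask: np.ndarray, markers: MarkerMap
) -> list[TruthSegment]:
    bp = markers.position_bp
    out = []
    for chrom, sl in markers.chrom_slices().items():
        idx = np.flatnonzero(auto_mask[sl])
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            out.append(
                TruthSegment(
                    sample_id,
                    chrom,
                    int(bp[sl.start + idx[s]]),
                    int(bp[sl.start + idx[e]]),
                    IBD_AUTOZYGOUS,
                )
            )
    return out


def gene_drop(
    pedigree: Pedigree,
    founders: FounderPool,
    markers: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[TruthSegment]]:
    """Drop founder haplotypes through the pedigree, tracking autozygosity.

    Truth segments are maximal runs of SNPs where both inherited haplotypes
    descend from the same founder haplotype; they are recorded *before*
    missingness and heterozygote errors are injected into the genotypes.
    """
    rng = rng or np.random.default_rng(config.seed)
    if set(pedigree.founders) - set(founders.founder_ids):
        raise ValueError("pedigree founders missing from the founder pool")
    bp = markers.position_bp
    chrom_slices = list(markers.chrom_slices().values())
    m_total = len(markers)

    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    founder_index = {f: k for k, f in enumerate(founders.founder_ids)}
    for ind, sire, dam in pedigree.entries:
        if sire is None and dam is None:
            k = founder_index[ind]
            alleles = founders.alleles[k].copy()
            # identical founder haplotypes are indistinguishable copies:
            # give them one ancestry label so a fully homozygous founder
            # transmits autozygosity
            second = 2 * k if np.array_equal(alleles[0], alleles[1]) else 2 * k + 1
            ancestry = np.stack(
                [
                    np.full(m_total, 2 * k, dtype=np.int32),
                    np.full(m_total, second, dtype=np.int32),
                ]
            )
            haplo[ind] = (alleles, ancestry)
        else:
            if sire is None or dam is None:
                raise ValueError(f"{ind}: both parents required for non-founders")
            gametes = []
            for parent in (sire, dam):
                p_all, p_anc = haplo[parent]
                gametes.append(
                    _meiosis(
                        p_all,
                        p_anc,
                        chrom_slices,
                        bp,
                        config.chromosome_length_bp,
                        config.chromosome_morgans,
                        rng,
                    )
                )
            alleles = np.stack([gametes[0][0], gametes[1][0]])
            ancestry = np.stack([gametes[0][1], gametes[1][1]])
            haplo[ind] = (alleles, ancestry)

    sample_ids = pedigree.ids
    codes = np.empty((len(sample_ids), m_total), dtype=np.int8)
    truth: list[TruthSegment] = []
    auto_masks = np.zeros((len(sample_ids), m_total), dtype=bool)
    for i, ind in enumerate(sample_ids):
        alleles, ancestry = haplo[ind]
        codes[i] = alleles[0].astype(np.int8) + alleles[1].astype(np.int8)
        auto = ancestry[0] == ancestry[1]
        auto_masks[i] = auto
        truth.extend(_autozygous_truth(ind, auto, markers))

    # noise: heterozygote errors inside IBD segments, then missingness
    if config.het_error_rate > 0:
        flip = auto_masks & (rng.random(codes.shape) < config.het_error_rate)
        codes[flip & ((codes == HOM_A) | (codes == HOM_B))] = HET
    if config.missing_rate > 0:
        codes[rng.random(codes.shape) < config.missing_rate] = MISSING

    gm = GenotypeMatrix(sample_ids, codes, markers)
    return gm, truth


# ---------------------------------------------------------------------------
# planted-segment generator


def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + 1:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


def plant_segments(
    markers: MarkerMap,
    planted_intervals: list[tuple[str, int, int]],
    n_individuals: int,
    carrier_fraction: float,
    background_het_rate: float = 0.35,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "ind",
) -> tuple[GenotypeMatrix, list[TruthSegment]]:
    """Write homozygous intervals into a heterozygous background.

    Background genotypes are i.i.d. (HET with the given rate, the remainder
    split between the homozygotes).  Per interval, round(carrier_fraction·n)
    individuals are drawn as carriers and receive a shared per-SNP homozygous
    pattern over the interval.  Overlapping intervals hitting the same
    individual are merged in the truth list with a warning.
    """
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    m = len(markers)
    bp = markers.position_bp
    chrom_slices = markers.chrom_slices()

    u = rng.random((n_individuals, m))
    h = background_het_rate
    codes = np.where(
        u < h, HET, np.where(u < h + (1 - h) / 2, HOM_A, HOM_B)
    ).astype(np.int8)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_individuals)]

    per_individual: dict[int, list[tuple[str, int, int]]] = {}
    n_carriers = int(round(carrier_fraction * n_individuals))
    for chrom, start, end in planted_intervals:
        sl = chrom_slices.get(str(chrom))
        if sl is None:
            raise ValueError(f"planted interval on unknown chromosome {chrom}")
        bp_c = bp[sl]
        i0 = int(np.searchsorted(bp_c, start, side="left"))
        i1 = int(np.searchsorted(bp_c, end, side="right")) - 1
        if i1 < i0 or start < 1 or end > bp_c[-1]:
            raise ValueError(f"planted interval {chrom}:{start}-{end} outside map")
        pattern = np.where(rng.random(i1 - i0 + 1) < 0.5, HOM_A, HOM_B).astype(np.int8)
        carriers = rng.choice(n_individuals, size=n_carriers, replace=False)
        for ind in carriers:
            codes[ind, sl.start + i0 : sl.start + i1 + 1] = pattern
            per_individual.setdefault(int(ind), []).append(
                (str(chrom), int(bp_c[i0]), int(bp_c[i1]))
            )

    truth: list[TruthSegment] = []
    for ind, ivs in sorted(per_individual.items()):
        merged = _merge_intervals(ivs)
        if len(merged) < len(ivs):
            warnings.warn(
                f"{sample_ids[ind]}: overlapping planted intervals merged"
            )
        truth.extend(
            TruthSegment(sample_ids[ind], chrom, s, e, PLANTED_HOMOZYGOUS)
            for chrom, s, e in merged
        )
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    return GenotypeMatrix(sample_ids, codes, markers), truth


# ---------------------------------------------------------------------------
# pedigree designs


def full_sib_pedigree(
    n_lines: int, n_offspring: int = 2, prefix: str = "L"
) -> tuple[Pedigree, list[str]]:
    """Independent lines of a full-sib mating whose offspring have F = 0.25.

    Each line: two founders → two full sibs → ``n_offspring`` children of
    the sib × sib mating.  Returns the pedigree and the offspring ids.
    """
    entries: list[tuple[str, str | None, str | None]] = []
    offspring: list[str] = []
    for k in range(n_lines):
        f1, f2 = f"{prefix}{k}.f1", f"{prefix}{k}.f2"
        s1, s2 = f"{prefix}{k}.s1", f"{prefix}{k}.s2"
        entries += [(f1, None, None), (f2, None, None), (s1, f1, f2), (s2, f1, f2)]
        for j in range(n_offspring):
            o = f"{prefix}{k}.o{j}"
            entries.append((o, s1, s2))
            offspring.append(o)
    return Pedigree(entries), offspring


def sib_chain_pedigree(
    n_lines: int, depth: int, n_offspring: int = 2, prefix: str = "L"
) -> tuple[Pedigree, dict[int, list[str]]]:
    """Repeated full-sib mating chains with sampled offspring per depth.

    Depth d offspring are children of the d-th sib × sib pair; their
    inbreeding coefficients follow the repeated-full-sib recursion
    F_1 = 0.25, F_2 = 0.375, F_3 = 0.5, ...  Returns the pedigree and a
    map depth → sampled offspring ids.
    """
    entries: list[tuple[str, str | None, str | None]] = []
    sampled: dict[int, list[str]] = {d: [] for d in range(1, depth + 1)}
    for k in range(n_lines):
        f1, f2 = f"{prefix}{k}.f1", f"{prefix}{k}.f2"
        entries += [(f1, None, None), (f2, None, None)]
        pair = (f1, f2)
        for d in range(1, depth + 1):
            a = f"{prefix}{k}.g{d}a"
            b = f"{prefix}{k}.g{d}b"
            entries += [(a, pair[0], pair[1]), (b, pair[0], pair[1])]
            for j in range(n_offspring):
                o = f"{prefix}{k}.g{d}o{j}"
                entries.append((o, a, b))
                sampled[d].append(o)
            pair = (a, b)
    return Pedigree(entries), sampled


def simulate_pedigree(
    pedigree: Pedigree, config: SimConfig
) -> tuple[GenotypeMatrix, list[TruthSegment], MarkerMap]:
    """Map + founders + gene drop under a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    markers = build_marker_map(config, rng)
    founders = simulate_founders(config, pedigree.founders, rng)
    gm, truth = gene_drop(pedigree, founders, markers, config, rng)
    return gm, truth, markers


def simulate_island_groups(
    seed: int,
    n_per_group: tuple[int, int] = (66, 73),
    n_chromosomes: int = 6,
    snps_per_chromosome: int = 2500,
    chromosome_length_mb: float = 100.0,
    hotspot_snps: int = 70,
    carrier_fraction: float = 0.8,
    background_het_rate: float = 0.35,
):
    """Two groups sharing one planted homozygosity hotspot.

    Chromosome 1 carries the shared hotspot, chromosome 2 a hotspot private
    to group A, chromosome 3 one private to group B; the remaining
    chromosomes are uniform background (the specificity control).  Hotspot
    SNPs total < 1% of the genome so the top-1% incidence threshold falls
    below the hotspot plateau.

    Returns (gm_a, gm_b, markers, shared, private_a, private_b) with the
    planted intervals as (chrom, start_bp, end_bp).
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        chromosome_length_mb=chromosome_length_mb,
    )
    markers = build_marker_map(config)
    bp = markers.position_bp
    slices = markers.chrom_slices()

    def interval(chrom: str, start_idx: int) -> tuple[str, int, int]:
        sl = slices[chrom]
        return (
            chrom,
            int(bp[sl.start + start_idx]),
            int(bp[sl.start + start_idx + hotspot_snps - 1]),
        )

    mid = snps_per_chromosome // 2
    shared = interval("1", mid)
    private_a = interval("2", mid)
    private_b = interval("3", mid)
    gm_a, _ = plant_segments(
        markers,
        [shared, private_a],
        n_per_group[0],
        carrier_fraction,
        background_het_rate,
        rng=rng,
        sample_prefix="A",
    )
    gm_b, _ = plant_segments(
        markers,
        [shared, private_b],
        n_per_group[1],
        carrier_fraction,
        background_het_rate,
        rng=rng,
        sample_prefix="B",
    )
    return gm_a, gm_b, markers, shared, private_a, private_b


def save_config(config: SimConfig, path) -> None:
    """Echo the full simulation configuration as YAML for provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
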