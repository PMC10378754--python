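"""Per-SNP ROH incidence, core-ROH consensus regions, and ROH-island calling.

An *island* is a population-level homozygosity hotspot: an uninterrupted
stretch of at least ``min_run`` SNPs that (a) lie inside a core ROH (a
consensus region covered by the ROH of at least ``min_carriers``
individuals) and (b) whose standardized in-ROH incidence strictly exceeds
the group's top-1% empirical threshold.  Standardization is genome-wide
within a group, so each group carries a single threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MarkerMap
from .roh import ROHSegment

__all__ = [
    "IncidenceTrack",
    "CoreROH",
    "ROHIsland",
    "ConservedIsland",
    "incidence",
    "core_roh",
    "island_threshold",
    "call_islands",
    "intersect_islands",
    "islands_to_frame",
    "conserved_to_frame",
]


@dataclass
class IncidenceTrack:
    """Per-SNP carrier counts c_j and standardized scores z_j for one group.

    ``z`` is None when the counts are constant (sd = 0), in which case no
    islands are callable.
    """

    counts: np.ndarray
    z: np.ndarray | None
    markers: MarkerMap
    n_individuals: int
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.markers.chromosome,
                "snp_id": self.markers.snp_id,
                "position_bp": self.markers.position_bp,
                "carrier_count": self.counts,
                "z": self.z if self.z is not None else np.nan,
            }
        )


@dataclass(frozen=True)
class CoreROH:
    """Consensus region covered by the ROH of >= min_carriers individuals."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_carriers: int  # minimum carrier count over the contained SNPs


@dataclass(frozen=True)
class ROHIsland:
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    group: str | None = None


@dataclass(frozen=True)
class ConservedIsland:
    """Intersection of two groups' islands on the same chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int
    source_a: ROHIsland
    source_b: ROHIsland


def _segment_snp_range(
    seg: ROHSegment, chrom_slices: dict[str, slice], bp: np.ndarray
) -> tuple[int, int]:
    """Global SNP-index range [i0, i1] covered by a segment."""
    if seg.chromosome not in chrom_slices:
        raise ValueError(f"segment on unknown chromosome {seg.chromosome}")
    sl = chrom_slices[seg.chromosome]
    bp_c = bp[sl]
    if seg.end_bp < bp_c[0] or seg.start_bp > bp_c[-1]:
        raise ValueError(
            f"segment {seg.chromosome}:{seg.start_bp}-{seg.end_bp} outside map range"
        )
    i0 = int(np.searchsorted(bp_c, seg.start_bp, side="left"))
    i1 = int(np.searchsorted(bp_c, seg.end_bp, side="right")) - 1
    return sl.start + i0, sl.start + i1


def incidence(
    segments: list[ROHSegment],
    markers: MarkerMap,
    n_individuals: int,
    group: str | None = None,
) -> IncidenceTrack:
    """Count, per SNP, the individuals whose ROH cover it, and standardize.

    Each individual contributes at most 1 to a SNP even if its segments
    overlap; z is computed genome-wide over all SNPs of the map.
    """
    m = len(markers)
    counts = np.zeros(m, dtype=np.int64)
    chrom_slices = markers.chrom_slices()
    bp = markers.position_bp
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for segs in by_sample.values():
        covered = np.zeros(m, dtype=bool)
        for seg in segs:
            i0, i1 = _segment_snp_range(seg, chrom_slices, bp)
            if i1 >= i0:
                covered[i0 : i1 + 1] = True
        counts += covered
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else None
    return IncidenceTrack(counts, z, markers, n_individuals, group)


def _index_runs(mask: np.ndarray, chrom_slices: dict[str, slice]):
    """Maximal True runs that never span a chromosome boundary."""
    for chrom, sl in chrom_slices.items():
        idx = np.flatnonzero(mask[sl])
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            yield chrom, sl.start + int(idx[s]), sl.start + int(idx[e])


def core_roh(
    segments: list[ROHSegment], markers: MarkerMap, min_carriers: int = 2
) -> list[CoreROH]:
    """Maximal runs of consecutive SNPs carried by >= min_carriers individuals."""
    n_ind = len({s.sample_id for s in segments})
    track = incidence(segments, markers, n_individuals=max(n_ind, 1))
    bp = markers.position_bp
    cores = []
    for chrom, i0, i1 in _index_runs(track.counts >= min_carriers, markers.chrom_slices()):
        cores.append(
            CoreROH(
                chromosome=chrom,
                start_bp=int(bp[i0]),
                end_bp=int(bp[i1]),
                n_snps=i1 - i0 + 1,
                n_carriers=int(track.counts[i0 : i1 + 1].min()),
            )
        )
    return cores


def island_threshold(
    track: IncidenceTrack, top_fraction: float = 0.01
) -> float | None:
    """Empirical (1 − top_fraction) quantile of the group's z scores.

    Linear-interpolation quantile; returns None when sd(c) = 0 (no islands
    callable).
    """
    if track.z is None:
        return None
    return float(np.quantile(track.z, 1.0 - top_fraction, method="linear"))


def call_islands(
    track: IncidenceTrack,
    cores: list[CoreROH],
    threshold: float | None,
    min_run: int = 3,
) -> list[ROHIsland]:
    """Maximal runs of >= min_run consecutive SNPs strictly above the
    threshold and inside a core ROH; bounds are the first/last SNP positions.
    """
    if threshold is None or track.z is None:
        return []
    markers = track.markers
    bp = markers.position_bp
    chrom_slices = markers.chrom_slices()
    in_core = np.zeros(len(markers), dtype=bool)
    for core in cores:
        sl = chrom_slices.get(core.chromosome)
        if sl is None:
            continue
        bp_c = bp[sl]
        i0 = int(np.searchsorted(bp_c, core.start_bp, side="left"))
        i1 = int(np.searchsorted(bp_c, core.end_bp, side="right")) - 1
        if i1 >= i0:
            in_core[sl.start + i0 : sl.start + i1 + 1] = True
    qualifying = (track.z > threshold) & in_core
    islands = []
    for chrom, i0, i1 in _index_runs(qualifying, chrom_slices):
        if i1 - i0 + 1 >= min_run:
            islands.append(
                ROHIsland(
                    chromosome=chrom,
                    start_bp=int(bp[i0]),
                    end_bp=int(bp[i1]),
                    n_snps=i1 - i0 + 1,
                    group=track.group,
                )
            )
    return islands


def intersect_islands(
    islands_a: list[ROHIsland], islands_b: list[ROHIsland]
) -> list[ConservedIsland]:
    """Pairwise same-chromosome intersections (>= 1 bp overlap) of two
    groups' islands, sorted by (chromosome, start)."""
    out = []
    for a in islands_a:
        for b in islands_b:
            if a.chromosome != b.chromosome:
                continue
            start = max(a.start_bp, b.start_bp)
            end = min(a.end_bp, b.end_bp)
            if start <= end:
                out.append(ConservedIsland(a.chromosome, start, end, a, b))
    from .genotypes import _chrom_key

    out.sort(key=lambda c: (_chrom_key(c.chromosome), c.start_bp, c.end_bp))
    return out


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [i.chromosome for i in islands],
            "start_bp": [i.start_bp for i in islands],
            "end_bp": [i.end_bp for i in islands],
            "n_snps": [i.n_snps for i in islands],
            "group": [i.group for i in islands],
        }
    )


def conserved_to_frame(conserved: list[ConservedIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in conserved],
            "start_bp": [c.start_bp for c in conserved],
            "end_bp": [c.end_bp for c in conserved],
            "group_a_start_bp": [c.source_a.start_bp for c in conserved],
            "group_a_end_bp": [c.source_a.end_bp for c in conserved],
            "group_a_n_snps": [c.source_a.n_snps for c in conserved],
            "group_b_start_bp": [c.source_b.start_bp for c in conserved],
            "group_b_end_bp": [c.source_b.end_bp for c in conserved],
            "group_b_n_snps": [c.source_b.n_snps for c in conserved],
        }
    )
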