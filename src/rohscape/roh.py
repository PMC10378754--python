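"""Sliding-window runs-of-homozygosity calling, F_ROH, and length-class tables.

The caller follows the PLINK ``--homozyg`` scanning scheme: a window of
``window_snps`` consecutive markers qualifies when it contains at most
``max_het_per_window`` heterozygotes and ``max_missing_per_window`` missing
calls; every SNP is scored by the fraction of the fully-contained windows
covering it that qualify; SNPs with score >= ``hit_fraction_threshold``
whose own call is not heterozygous are chained into candidate runs, which
must then clear minimum SNP-count, minimum length, maximum inter-SNP gap
and marker-density filters.

Segment lengths are end_bp − start_bp + 1 (1-based inclusive), matching the
convention of printed ROH coordinates; the off-by-one versus PLINK's
end − start is immaterial at Mb scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, MISSING

__all__ = [
    "ROHParams",
    "ROHSegment",
    "FrohRecord",
    "GENOME_LENGTH_MB_SSCROFA11",
    "window_qualifies",
    "snp_hit_fractions",
    "call_roh",
    "f_roh",
    "froh_table",
    "length_class_summary",
    "segments_to_frame",
]

#: Autosomal genome length of the Sscrofa 11.1 assembly, the F_ROH denominator.
GENOME_LENGTH_MB_SSCROFA11: float = 2265.77

DEFAULT_LENGTH_CLASS_EDGES_MB: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class ROHParams:
    """Window and run filters for the sliding-window ROH scan.

    The window geometry (50 SNPs, ≤1 heterozygote, ≤1 missing, ≥50 SNPs per
    run) is the published protocol; the hit-fraction threshold, minimum run
    length, maximum gap and density ceiling default to the PLINK 1.9
    ``--homozyg`` defaults.
    """

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    min_snps_per_roh: int = 50
    hit_fraction_threshold: float = 0.05
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0  # max kb of span allowed per SNP

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        for name in (
            "max_het_per_window",
            "max_missing_per_window",
            "min_snps_per_roh",
            "hit_fraction_threshold",
            "min_length_kb",
            "max_gap_kb",
            "min_density_kb_per_snp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: 1-based inclusive bp bounds of its first/last SNP."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("ROHSegment start_bp > end_bp")

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6


@dataclass(frozen=True)
class FrohRecord:
    sample_id: str
    n_segments: int
    sum_roh_mb: float
    genome_length_mb: float
    f_roh: float


def window_qualifies(codes: np.ndarray, params: ROHParams) -> bool:
    """A window passes with at most the allowed heterozygote and missing calls."""
    codes = np.asarray(codes)
    if codes.shape != (params.window_snps,):
        raise ValueError(
            f"window must hold exactly {params.window_snps} codes, got {codes.shape}"
        )
    return bool(
        (codes == HET).sum() <= params.max_het_per_window
        and (codes == MISSING).sum() <= params.max_missing_per_window
    )


def snp_hit_fractions(codes: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP fraction of qualifying windows among the windows covering it.

    Only windows fully contained in the chromosome count; chromosomes shorter
    than the window yield all-zero fractions.
    """
    codes = np.asarray(codes)
    m = codes.shape[0]
    w = params.window_snps
    if m < w:
        return np.zeros(m)
    het = np.concatenate(([0], np.cumsum(codes == HET)))
    mis = np.concatenate(([0], np.cumsum(codes == MISSING)))
    het_in = het[w:] - het[:-w]  # window starting at k -> index k
    mis_in = mis[w:] - mis[:-w]
    ok = (het_in <= params.max_het_per_window) & (
        mis_in <= params.max_missing_per_window
    )
    cok = np.concatenate(([0], np.cumsum(ok)))
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, m - w)
    return (cok[hi + 1] - cok[lo]) / (hi - lo + 1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _segments_for_individual(
    codes: np.ndarray,
    bp: np.ndarray,
    chrom: str,
    sample_id: str,
    params: ROHParams,
) -> list[ROHSegment]:
    frac = snp_hit_fractions(codes, params)
    marked = (frac >= params.hit_fraction_threshold) & (codes != HET)
    out: list[ROHSegment] = []
    for i0, i1 in _runs(marked):
        # trim missing calls off the run ends
        while i0 <= i1 and codes[i0] == MISSING:
            i0 += 1
        while i1 >= i0 and codes[i1] == MISSING:
            i1 -= 1
        if i0 > i1:
            continue
        # split where adjacent SNPs are farther apart than the gap ceiling
        gaps = np.diff(bp[i0 : i1 + 1])
        cuts = np.flatnonzero(gaps > params.max_gap_kb * 1000.0)
        bounds = [i0] + [i0 + int(c) + 1 for c in cuts] + [i1 + 1]
        for s, e in zip(bounds[:-1], bounds[1:]):
            e -= 1
            # re-trim missing at the new boundaries
            while s <= e and codes[s] == MISSING:
                s += 1
            while e >= s and codes[e] == MISSING:
                e -= 1
            if s > e:
                continue
            n_snps = e - s + 1
            length_kb = (bp[e] - bp[s] + 1) / 1000.0
            if n_snps < params.min_snps_per_roh:
                continue
            if length_kb < params.min_length_kb:
                continue
            if length_kb / n_snps > params.min_density_kb_per_snp:
                continue
            out.append(
                ROHSegment(sample_id, chrom, int(bp[s]), int(bp[e]), n_snps)
            )
    return out


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH for every individual on every chromosome of the matrix.

    Expects a QC'd, autosome-restricted matrix; the marker map's sort
    invariant guarantees windows never straddle chromosomes.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    bp = gm.markers.position_bp
    for chrom, sl in gm.markers.chrom_slices().items():
        bp_c = bp[sl]
        block = gm.codes[:, sl]
        for i, sample_id in enumerate(gm.sample_ids):
            segments.extend(
                _segments_for_individual(block[i], bp_c, chrom, sample_id, params)
            )
    return segments


def f_roh(
    segments: list[ROHSegment],
    genome_length_mb: float = GENOME_LENGTH_MB_SSCROFA11,
    sample_id: str | None = None,
) -> FrohRecord:
    """F_ROH = ΣL_ROH / L for one individual's segments."""
    if genome_length_mb <= 0:
        raise ValueError("genome_length_mb must be positive")
    ids = {s.sample_id for s in segments}
    if len(ids) > 1:
        raise ValueError(f"segments from multiple individuals: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    total_mb = sum(s.length_mb for s in segments)
    return FrohRecord(
        sample_id=sample_id,
        n_segments=len(segments),
        sum_roh_mb=total_mb,
        genome_length_mb=genome_length_mb,
        f_roh=total_mb / genome_length_mb,
    )


def froh_table(
    segments: list[ROHSegment],
    sample_ids: list[str],
    genome_length_mb: float = GENOME_LENGTH_MB_SSCROFA11,
) -> pd.DataFrame:
    """Per-individual ROH count, ΣL_ROH (Mb) and F_ROH, including
    individuals with zero segments."""
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in sample_ids}
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    records = [
        f_roh(segs, genome_length_mb, sample_id=sid)
        for sid, segs in by_sample.items()
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "n_roh": [r.n_segments for r in records],
            "sum_roh_mb": [r.sum_roh_mb for r in records],
            "f_roh": [r.f_roh for r in records],
        }
    )


def _class_labels(edges: tuple[float, ...]) -> list[str]:
    labels = [f"<{edges[0]:g} Mb"]
    labels += [f"{lo:g}-{hi:g} Mb" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]:g} Mb")
    return labels


def add_totals(frame: pd.DataFrame) -> pd.DataFrame:
    """Append the totals row of a length-class table: counts and coverages
    sum; mean±sd SNPs/ROH columns are left blank."""
    total = {
        "roh_class": "Total",
        "roh_count": frame["roh_count"].sum(),
        "snps_per_roh_mean": np.nan,
        "snps_per_roh_sd": np.nan,
        "pct_genome_coverage": frame["pct_genome_coverage"].sum(),
    }
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def length_class_summary(
    segments: list[ROHSegment],
    n_individuals: int,
    genome_length_mb: float = GENOME_LENGTH_MB_SSCROFA11,
    class_edges: tuple[float, ...] = DEFAULT_LENGTH_CLASS_EDGES_MB,
) -> pd.DataFrame:
    """Per-length-class ROH count, mean±sd SNPs/ROH and % genome coverage.

    Classes are left-closed: [0,2), [2,4), [4,8), [8,16), [16,∞) Mb with the
    default edges, so a segment of exactly 4.0 Mb falls in the 4–8 Mb class.
    Coverage = 100 · (mean per-individual summed class length) / L.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    lengths = np.array([s.length_mb for s in segments])
    snps = np.array([s.n_snps for s in segments])
    edges = np.array([0.0, *class_edges, np.inf])
    labels = _class_labels(tuple(class_edges))
    cls = np.digitize(lengths, edges[1:-1], right=False) if len(segments) else np.array([], int)
    rows = []
    for k, label in enumerate(labels):
        in_k = cls == k
        count = int(in_k.sum())
        rows.append(
            {
                "roh_class": label,
                "roh_count": count,
                "snps_per_roh_mean": float(snps[in_k].mean()) if count else np.nan,
                "snps_per_roh_sd": float(snps[in_k].std(ddof=1))
                if count > 1
                else np.nan,
                "pct_genome_coverage": 100.0
                * (lengths[in_k].sum() / n_individuals)
                / genome_length_mb,
            }
        )
    return add_totals(pd.DataFrame(rows))


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_mb": [s.length_mb for s in segments],
        }
    )
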