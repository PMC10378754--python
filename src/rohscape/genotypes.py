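"""Genotype data model, PLINK text PED/MAP I/O, QC filters and BED export.

Genotypes are held as a dense individuals × markers byte matrix with four
codes (:data:`HOM_A`, :data:`HET`, :data:`HOM_B`, :data:`MISSING`).  The
HOM_A/HOM_B distinction follows the per-marker alphabetical order of the
allele letters; it is an I/O convention only — every downstream statistic
(MAF, HWE, ROH) is symmetric under swapping the two homozygote labels.

Coordinates are 1-based inclusive base pairs internally; BED export converts
to the standard 0-based half-open convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_A",
    "HET",
    "HOM_B",
    "MISSING",
    "AUTOSOMES_PIG",
    "FileFormatError",
    "DataError",
    "EmptyResultError",
    "MarkerMap",
    "GenotypeMatrix",
    "QCParams",
    "QCReport",
    "read_ped_map",
    "write_ped_map",
    "qc_filter",
    "subset_autosomes",
    "write_bed_intervals",
    "read_bed_intervals",
]

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = 3

#: The 18 pig (Sus scrofa) autosomes, the chromosome set every windowed
#: computation is restricted to by default.
AUTOSOMES_PIG: frozenset[str] = frozenset(str(i) for i in range(1, 19))


class FileFormatError(ValueError):
    """Malformed PED/MAP/BED input (wrong column counts, non-integer bp...)."""


class DataError(ValueError):
    """Structurally valid file with inadmissible content (>2 alleles etc.)."""


class EmptyResultError(RuntimeError):
    """An operation removed every sample."""


def _chrom_key(label: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosome labels first, in numeric order."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


class MarkerMap:
    """Ordered marker coordinates: (chromosome, snp_id, position_bp).

    Markers are strictly sorted by (chromosome, position_bp); duplicate
    (chromosome, position_bp) pairs are rejected.  Positions are 1-based.
    """

    def __init__(self, frame: pd.DataFrame, group: str | None = None):
        required = {"chromosome", "snp_id", "position_bp"}
        if not required.issubset(frame.columns):
            raise FileFormatError(
                f"marker map needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        frame = frame.reset_index(drop=True).copy()
        frame["chromosome"] = frame["chromosome"].astype(str)
        frame["snp_id"] = frame["snp_id"].astype(str)
        bp = pd.to_numeric(frame["position_bp"], errors="coerce")
        if bp.isna().any() or (bp != bp.astype("int64", errors="ignore")).any():
            raise FileFormatError("position_bp must be integer")
        frame["position_bp"] = bp.astype(np.int64)
        if (frame["position_bp"] < 1).any():
            raise FileFormatError("position_bp must be >= 1 (1-based coordinates)")
        if "cm" not in frame.columns:
            frame["cm"] = 0.0
        keys = list(zip(frame["chromosome"].map(_chrom_key), frame["position_bp"]))
        order = sorted(range(len(keys)), key=keys.__getitem__)
        if len(set(keys)) != len(keys):
            dup = frame.loc[frame.duplicated(["chromosome", "position_bp"]), "snp_id"]
            raise DataError(f"duplicate (chromosome, position_bp) at {list(dup[:3])}")
        self._sort_order = np.asarray(order, dtype=np.intp)
        self.frame = frame.iloc[order].reset_index(drop=True)
        self.group = group

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int]],
        group: str | None = None,
    ) -> "MarkerMap":
        frame = pd.DataFrame(records, columns=["chromosome", "snp_id", "position_bp"])
        return cls(frame, group=group)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chromosome(self) -> np.ndarray:
        return self.frame["chromosome"].to_numpy()

    @property
    def snp_id(self) -> np.ndarray:
        return self.frame["snp_id"].to_numpy()

    @property
    def position_bp(self) -> np.ndarray:
        return self.frame["position_bp"].to_numpy()

    @property
    def sort_order(self) -> np.ndarray:
        """Permutation that carried the input rows into sorted map order."""
        return self._sort_order

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice for every chromosome, in map order."""
        out: dict[str, slice] = {}
        chrom = self.chromosome
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[chrom[start]] = slice(start, i)
                start = i
        return out

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.frame.iloc[idx], group=self.group)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerMap) and self.frame[
            ["chromosome", "snp_id", "position_bp"]
        ].equals(other.frame[["chromosome", "snp_id", "position_bp"]])


@dataclass
class GenotypeMatrix:
    """Individuals × markers genotype codes with the linked marker map.

    ``codes`` is int8, one byte per cell (~80 × 60,000 cells is ~4.8 MB).
    ``alleles`` holds the two allele letters per marker in alphabetical
    order (allele A first); markers where only one (or no) allele was ever
    observed carry placeholder letters for the unseen slot.
    """

    sample_ids: list[str]
    codes: np.ndarray
    markers: MarkerMap
    alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise DataError("codes must be 2-D (samples × markers)")
        if self.codes.shape != (len(self.sample_ids), len(self.markers)):
            raise DataError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.markers)} markers)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if self.codes.size and (
            self.codes.min() < HOM_A or self.codes.max() > MISSING
        ):
            raise DataError("genotype codes must be in {HOM_A, HET, HOM_B, MISSING}")
        if self.alleles is None:
            al = np.empty((len(self.markers), 2), dtype=object)
            al[:, 0] = "A"
            al[:, 1] = "B"
            self.alleles = al
        elif self.alleles.shape != (len(self.markers), 2):
            raise DataError("alleles must be (n_markers, 2)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - (self.codes == MISSING).mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - (self.codes == MISSING).mean(axis=0)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.codes[idx],
            self.markers,
            self.alleles,
        )

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.codes[:, idx],
            self.markers.take(idx),
            self.alleles[idx],
        )

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker n_AA / n_AB / n_BB / n_missing counts."""
        return pd.DataFrame(
            {
                "snp_id": self.markers.snp_id,
                "n_AA": (self.codes == HOM_A).sum(axis=0),
                "n_AB": (self.codes == HET).sum(axis=0),
                "n_BB": (self.codes == HOM_B).sum(axis=0),
                "n_missing": (self.codes == MISSING).sum(axis=0),
            }
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class QCParams:
    """Call-rate QC thresholds; comparisons are strict ('lower than')."""

    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    autosomes: frozenset[str] = AUTOSOMES_PIG
    samples_first: bool = True

    def __post_init__(self) -> None:
        for r in (self.min_sample_call_rate, self.min_snp_call_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("call-rate thresholds must be in [0, 1]")


@dataclass
class QCReport:
    removed_samples: list[str]
    removed_snps: list[str]
    n_samples_before: int
    n_samples_after: int
    n_snps_before: int
    n_snps_after: int
    params: QCParams

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", s) for s in self.removed_samples]
        rows += [("snp", s) for s in self.removed_snps]
        return pd.DataFrame(rows, columns=["kind", "id"])

    def summary(self) -> str:
        return (
            f"samples {self.n_samples_before} -> {self.n_samples_after} "
            f"({len(self.removed_samples)} removed); "
            f"snps {self.n_snps_before} -> {self.n_snps_after} "
            f"({len(self.removed_snps)} removed)"
        )


# ---------------------------------------------------------------------------
# PED/MAP I/O


def _read_map_frame(map_path: str | Path) -> MarkerMap:
    try:
        raw = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{map_path}: empty MAP file") from None
    if raw.shape[1] != 4:
        raise FileFormatError(
            f"{map_path}: MAP must have 4 columns (chrom, id, cM, bp), got {raw.shape[1]}"
        )
    bp = pd.to_numeric(raw[3], errors="coerce")
    if bp.isna().any():
        bad = raw.loc[bp.isna(), 1].iloc[0]
        raise FileFormatError(f"{map_path}: non-integer bp at marker {bad}")
    frame = pd.DataFrame(
        {
            "chromosome": raw[0],
            "snp_id": raw[1],
            "cm": pd.to_numeric(raw[2], errors="coerce").fillna(0.0),
            "position_bp": bp,
        }
    )
    return MarkerMap(frame)


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    Markers are re-sorted to (chromosome, position_bp) order with PED
    columns permuted consistently.  Per marker, allele letters are mapped
    alphabetically: the lexicographically smaller letter is allele A, so
    HOM_A means homozygous for that allele.  Missing allele code is ``"0"``;
    a half-missing pair is treated as a missing genotype.
    """
    mmap = _read_map_frame(map_path)
    m = len(mmap)
    perm = mmap.sort_order

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FileFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2×{m} markers), got {len(fields)}"
                )
            sample_ids.append(fields[1])
            rows.append(fields[6:])
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise DataError(f"{ped_path}: duplicate individual IDs")

    codes = np.full((n, m), MISSING, dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    if n:
        allele_arr = np.array(rows, dtype=object)
        a1 = allele_arr[:, 0::2][:, perm]
        a2 = allele_arr[:, 1::2][:, perm]
    for j in range(m):
        if n == 0:
            alleles[j] = ("A", "B")
            continue
        col1, col2 = a1[:, j], a2[:, j]
        observed = sorted({*col1, *col2} - {"0"})
        if len(observed) > 2:
            raise DataError(
                f"marker {mmap.snp_id[j]}: more than two alleles {observed}"
            )
        aa = observed[0] if observed else "A"
        bb = observed[1] if len(observed) > 1 else ("B" if aa != "B" else "C")
        alleles[j] = (aa, bb)
        miss = (col1 == "0") | (col2 == "0")
        hom_a = (col1 == aa) & (col2 == aa)
        hom_b = (col1 == bb) & (col2 == bb)
        codes[:, j] = np.select(
            [miss, hom_a, hom_b], [MISSING, HOM_A, HOM_B], default=HET
        )
    return GenotypeMatrix(sample_ids, codes, mmap, alleles)


def write_ped_map(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PLINK text PED/MAP round-trippable by :func:`read_ped_map`."""
    mf = gm.markers.frame
    with open(map_path, "w") as fh:
        for chrom, sid, cm, bp in zip(
            mf["chromosome"], mf["snp_id"], mf["cm"], mf["position_bp"]
        ):
            fh.write(f"{chrom}\t{sid}\t{cm:g}\t{bp}\n")

    # genotype code -> the two allele letters, per marker
    lut = np.empty((gm.n_markers, 4, 2), dtype=object)
    lut[:, HOM_A, 0] = lut[:, HOM_A, 1] = gm.alleles[:, 0]
    lut[:, HET, 0] = gm.alleles[:, 0]
    lut[:, HET, 1] = gm.alleles[:, 1]
    lut[:, HOM_B, 0] = lut[:, HOM_B, 1] = gm.alleles[:, 1]
    lut[:, MISSING, 0] = lut[:, MISSING, 1] = "0"
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            pairs = lut[np.arange(gm.n_markers), gm.codes[i]]
            body = "\t".join(f"{p[0]}\t{p[1]}" for p in pairs)
            lead = f"{sid}\t{sid}\t0\t0\t0\t-9"
            fh.write(lead + ("\t" + body if body else "") + "\n")


# ---------------------------------------------------------------------------
# QC


def qc_filter(gm: GenotypeMatrix, params: QCParams | None = None) -> tuple[
    GenotypeMatrix, QCReport
]:
    """Remove low-call-rate samples, then low-call-rate SNPs.

    Sample call rates are evaluated on the full marker set; SNP call rates
    are then computed on the surviving samples only.  Thresholds are strict:
    a call rate exactly at the threshold is kept.  ``params.samples_first``
    flips the order if needed.
    """
    params = params or QCParams()

    def _drop_samples(g: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
        keep = g.sample_call_rates() >= params.min_sample_call_rate
        removed = [s for s, k in zip(g.sample_ids, keep) if not k]
        return g.take_samples(np.flatnonzero(keep)), removed

    def _drop_snps(g: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
        keep = g.snp_call_rates() >= params.min_snp_call_rate
        removed = list(g.markers.snp_id[~keep])
        return g.take_markers(np.flatnonzero(keep)), removed

    if params.samples_first:
        out, rs = _drop_samples(gm)
        out, rm = _drop_snps(out)
    else:
        out, rm = _drop_snps(gm)
        out, rs = _drop_samples(out)
    if gm.n_samples and not out.n_samples:
        raise EmptyResultError("QC removed every sample")
    report = QCReport(
        removed_samples=rs,
        removed_snps=rm,
        n_samples_before=gm.n_samples,
        n_samples_after=out.n_samples,
        n_snps_before=gm.n_markers,
        n_snps_after=out.n_markers,
        params=params,
    )
    return out, report


def subset_autosomes(
    gm: GenotypeMatrix, autosomes: Iterable[str] = AUTOSOMES_PIG
) -> GenotypeMatrix:
    """Keep only markers on the given chromosomes, order preserved."""
    auto = {str(a) for a in autosomes}
    keep = np.array([c in auto for c in gm.markers.chromosome])
    if not keep.any():
        warnings.warn("subset_autosomes: no markers on the requested chromosomes")
    return gm.take_markers(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# BED interval export


def _as_interval(iv) -> tuple[str, int, int, str]:
    if hasattr(iv, "chromosome"):
        name = getattr(iv, "name", "") or getattr(iv, "sample_id", "") or "."
        return str(iv.chromosome), int(iv.start_bp), int(iv.end_bp), str(name)
    chrom, start, end, *rest = iv
    return str(chrom), int(start), int(end), str(rest[0]) if rest else "."


def write_bed_intervals(intervals: Sequence, path: str | Path) -> None:
    """Write 1-based-inclusive intervals as standard BED (0-based half-open).

    start_bed = start_bp - 1, end_bed = end_bp; output sorted by
    (chromosome, start).  Accepts tuples ``(chrom, start_bp, end_bp[, name])``
    or any object with chromosome/start_bp/end_bp attributes.
    """
    parsed = [_as_interval(iv) for iv in intervals]
    for chrom, start, end, _ in parsed:
        if start > end:
            raise DataError(f"interval start {start} > end {end} on chromosome {chrom}")
    parsed.sort(key=lambda t: (_chrom_key(t[0]), t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for chrom, start, end, name in parsed:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED back to internal 1-based inclusive intervals."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out
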