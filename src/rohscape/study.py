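"""End-to-end two-group study: QC → MAF/HWE → ROH → F_ROH → islands → comparison.

Runs each group through call-rate QC, autosome restriction, MAF/HWE
summaries, sliding-window ROH detection, per-individual F_ROH, the
length-class table, per-SNP incidence, core-ROH consensus and island
calling, then intersects the two groups' islands and tests the group means
(pooled-variance Student t by default, Welch on request).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import islands as isl
from . import qc_stats, roh
from .roh import GENOME_LENGTH_MB_SSCROFA11, ROHParams
from .genotypes import (
    AUTOSOMES_PIG,
    GenotypeMatrix,
    QCParams,
    QCReport,
    qc_filter,
    read_ped_map,
    subset_autosomes,
    write_bed_intervals,
)

__all__ = [
    "StudyConfig",
    "GroupResult",
    "ComparisonReport",
    "run_study",
    "two_sample_mean_test",
    "relative_change",
]

logger = logging.getLogger("rohscape")


@dataclass
class StudyConfig:
    """Inputs and parameters of a two-group ROH comparison.

    Either PED/MAP paths or in-memory matrices may be supplied per group.
    QC is applied to each group independently.
    """

    group_a_ped: str | None = None
    group_a_map: str | None = None
    group_b_ped: str | None = None
    group_b_map: str | None = None
    label_a: str = "A"
    label_b: str = "B"
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    top_fraction: float = 0.01
    min_run: int = 3
    min_carriers: int = 2
    genome_length_mb: float = GENOME_LENGTH_MB_SSCROFA11
    autosomes: frozenset[str] = AUTOSOMES_PIG
    alpha: float = 0.05
    welch: bool = False
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "roh" in raw:
            raw["roh"] = ROHParams(**raw["roh"])
        if "autosomes" in raw:
            raw["autosomes"] = frozenset(str(c) for c in raw["autosomes"])
        return cls(**raw)


@dataclass
class GroupResult:
    label: str
    qc_report: QCReport
    matrix: GenotypeMatrix
    maf_spectrum: qc_stats.MafSpectrum
    pct_hwe_disequilibrium: float
    pct_hom_excess: float
    segments: list[roh.ROHSegment]
    froh: pd.DataFrame
    length_classes: pd.DataFrame
    track: isl.IncidenceTrack
    cores: list[isl.CoreROH]
    threshold: float | None
    islands: list[isl.ROHIsland]

    @property
    def total_roh(self) -> int:
        return len(self.segments)

    @property
    def genome_coverage_pct(self) -> float:
        return 100.0 * self.froh["f_roh"].mean()


@dataclass
class ComparisonReport:
    group_a: GroupResult
    group_b: GroupResult
    conserved: list[isl.ConservedIsland]
    roh_count_test: tuple[float, int, float]
    froh_test: tuple[float, int, float]
    froh_relative_change_pct: float

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for g in (self.group_a, self.group_b):
            rows.append(
                {
                    "group": g.label,
                    "n_individuals": g.matrix.n_samples,
                    "n_snps": g.matrix.n_markers,
                    "pct_polymorphic": g.maf_spectrum.percent_polymorphic,
                    "pct_hwe_disequilibrium": g.pct_hwe_disequilibrium,
                    "pct_hom_excess": g.pct_hom_excess,
                    "total_roh": g.total_roh,
                    "genome_coverage_pct": g.genome_coverage_pct,
                    "mean_roh_per_individual": g.froh["n_roh"].mean(),
                    "sd_roh_per_individual": g.froh["n_roh"].std(ddof=1),
                    "mean_sum_roh_mb": g.froh["sum_roh_mb"].mean(),
                    "sd_sum_roh_mb": g.froh["sum_roh_mb"].std(ddof=1),
                    "mean_f_roh": g.froh["f_roh"].mean(),
                    "sd_f_roh": g.froh["f_roh"].std(ddof=1),
                    "n_cores": len(g.cores),
                    "n_islands": len(g.islands),
                }
            )
        return pd.DataFrame(rows)

    def tests_frame(self) -> pd.DataFrame:
        t1, df1, p1 = self.roh_count_test
        t2, df2, p2 = self.froh_test
        return pd.DataFrame(
            {
                "comparison": ["roh_count", "f_roh"],
                "t": [t1, t2],
                "df": [df1, df2],
                "p": [p1, p2],
            }
        )

    def write(self, out_dir: str | Path) -> None:
        """Emit all report tables (TSV) and BED exports deterministically."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g, suffix in ((self.group_a, "a"), (self.group_b, "b")):
            g.qc_report.to_frame().to_csv(
                out / f"qc_report_{suffix}.tsv", sep="\t", index=False
            )
            g.maf_spectrum.to_frame().to_csv(
                out / f"maf_spectrum_{suffix}.tsv", sep="\t", index=False
            )
            roh.segments_to_frame(g.segments).to_csv(
                out / f"roh_segments_{suffix}.tsv", sep="\t", index=False
            )
            g.froh.to_csv(out / f"froh_{suffix}.tsv", sep="\t", index=False)
            g.length_classes.to_csv(
                out / f"length_classes_{suffix}.tsv", sep="\t", index=False
            )
            g.track.to_frame().to_csv(
                out / f"incidence_{suffix}.tsv", sep="\t", index=False
            )
            write_bed_intervals(g.cores, out / f"cores_{suffix}.bed")
            write_bed_intervals(g.islands, out / f"islands_{suffix}.bed")
        isl.conserved_to_frame(self.conserved).to_csv(
            out / "conserved_islands.tsv", sep="\t", index=False
        )
        self.summary_frame().to_csv(out / "comparison.tsv", sep="\t", index=False)
        self.tests_frame().to_csv(out / "tests.tsv", sep="\t", index=False)


def two_sample_mean_test(
    values_a, values_b, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t test of the group means.

    Pooled-variance Student test by default (df = n_a + n_b − 2); Welch when
    ``pooled=False``.  Two groups with zero variance and equal means return
    (0, df, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        df = na + nb - 2 if pooled else float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), df, 0.0
    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def relative_change(mean_a: float, mean_b: float) -> float:
    """Percent change from mean_a to mean_b: 100 · (mean_a − mean_b)/mean_a."""
    if mean_a == 0:
        return float("nan")
    return 100.0 * (mean_a - mean_b) / mean_a


def _analyse_group(
    gm: GenotypeMatrix, label: str, config: StudyConfig
) -> GroupResult:
    filtered, qc_report = qc_filter(gm, config.qc)
    logger.info("[%s] QC: %s", label, qc_report.summary())
    auto = subset_autosomes(filtered, config.autosomes)
    spectrum = qc_stats.maf_spectrum(auto)
    poly = auto.take_markers(
        np.flatnonzero(~np.isnan(spectrum.maf) & (spectrum.maf > 0))
    )
    pct_diseq, pct_hom = qc_stats.hwe_summary(poly, config.alpha)
    segments = roh.call_roh(auto, config.roh)
    froh = roh.froh_table(segments, auto.sample_ids, config.genome_length_mb)
    length_classes = roh.length_class_summary(
        segments, auto.n_samples, config.genome_length_mb
    )
    track = isl.incidence(segments, auto.markers, auto.n_samples, group=label)
    cores = isl.core_roh(segments, auto.markers, config.min_carriers)
    threshold = isl.island_threshold(track, config.top_fraction)
    called = isl.call_islands(track, cores, threshold, config.min_run)
    logger.info(
        "[%s] %d ROH, %d cores, %d islands (threshold %s)",
        label,
        len(segments),
        len(cores),
        len(called),
        f"{threshold:.3f}" if threshold is not None else "n/a",
    )
    return GroupResult(
        label=label,
        qc_report=qc_report,
        matrix=auto,
        maf_spectrum=spectrum,
        pct_hwe_disequilibrium=pct_diseq,
        pct_hom_excess=pct_hom,
        segments=segments,
        froh=froh,
        length_classes=length_classes,
        track=track,
        cores=cores,
        threshold=threshold,
        islands=called,
    )


def run_study(
    config: StudyConfig,
    gm_a: GenotypeMatrix | None = None,
    gm_b: GenotypeMatrix | None = None,
) -> ComparisonReport:
    """Run the full two-group comparison; returns the report (and writes all
    tables when ``config.out_dir`` is set)."""
    if gm_a is None:
        if not (config.group_a_ped and config.group_a_map):
            raise ValueError("group A: provide a matrix or PED/MAP paths")
        gm_a = read_ped_map(config.group_a_ped, config.group_a_map)
    if gm_b is None:
        if not (config.group_b_ped and config.group_b_map):
            raise ValueError("group B: provide a matrix or PED/MAP paths")
        gm_b = read_ped_map(config.group_b_ped, config.group_b_map)

    res_a = _analyse_group(gm_a, config.label_a, config)
    res_b = _analyse_group(gm_b, config.label_b, config)
    conserved = isl.intersect_islands(res_a.islands, res_b.islands)

    pooled = not config.welch
    roh_test = two_sample_mean_test(
        res_a.froh["n_roh"], res_b.froh["n_roh"], pooled=pooled
    )
    froh_test = two_sample_mean_test(
        res_a.froh["f_roh"], res_b.froh["f_roh"], pooled=pooled
    )
    rel = relative_change(res_a.froh["f_roh"].mean(), res_b.froh["f_roh"].mean())
    report = ComparisonReport(
        group_a=res_a,
        group_b=res_b,
        conserved=conserved,
        roh_count_test=roh_test,
        froh_test=froh_test,
        froh_relative_change_pct=rel,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
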