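"""PED/MAP I/O, genotype data model, call-rate QC and BED export."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rohscape.genotypes import (
    DataError,
    EmptyResultError,
    FileFormatError,
    GenotypeMatrix,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    MarkerMap,
    QCParams,
    qc_filter,
    read_bed_intervals,
    read_ped_map,
    subset_autosomes,
    write_bed_intervals,
    write_ped_map,
)

from conftest import make_map, random_codes, random_matrix


class TestMarkerMap:
    def test_sorts_by_chromosome_then_position(self):
        mm = MarkerMap.from_records(
            [("2", "b", 50), ("1", "a", 200), ("1", "c", 100), ("10", "d", 10)]
        )
        assert list(mm.snp_id) == ["c", "a", "b", "d"]
        assert list(mm.chromosome) == ["1", "1", "2", "10"]

    def test_rejects_duplicate_positions(self):
        with pytest.raises(DataError, match="duplicate"):
            MarkerMap.from_records([("1", "a", 5), ("1", "b", 5)])

    def test_rejects_zero_position(self):
        with pytest.raises(FileFormatError):
            MarkerMap.from_records([("1", "a", 0)])

    def test_chrom_slices_are_contiguous_and_cover(self):
        mm = make_map({"1": 3, "2": 2})
        slices = mm.chrom_slices()
        assert slices == {"1": slice(0, 3), "2": slice(3, 5)}


class TestPedMapIO:
    def _write(self, tmp_path, ped_lines, map_lines):
        ped = tmp_path / "g.ped"
        mp = tmp_path / "g.map"
        ped.write_text("".join(line + "\n" for line in ped_lines))
        mp.write_text("".join(line + "\n" for line in map_lines))
        return ped, mp

    def test_allele_coding_and_missing(self, tmp_path):
        # alleles {A, G}: 'A A' -> HOM_A (alphabetical), '0 0' -> MISSING
        ped, mp = self._write(
            tmp_path,
            [
                "f1 i1 0 0 0 -9 A A G G",
                "f2 i2 0 0 0 -9 0 0 A G",
            ],
            ["1 snp1 0 100", "1 snp2 0 200"],
        )
        gm = read_ped_map(ped, mp)
        assert gm.codes[0, 0] == HOM_A
        assert gm.codes[0, 1] == HOM_B
        assert gm.codes[1, 0] == MISSING
        assert gm.codes[1, 1] == HET
        assert tuple(gm.alleles[1]) == ("A", "G")

    def test_unsorted_map_permutes_ped_columns(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            ["f i 0 0 0 -9 A A C G"],
            ["1 late 0 500", "1 early 0 100"],
        )
        gm = read_ped_map(ped, mp)
        assert list(gm.markers.snp_id) == ["early", "late"]
        assert gm.codes[0, 0] == HET  # the C/G genotype moved to column 0
        assert gm.codes[0, 1] == HOM_A

    def test_column_count_mismatch_raises(self, tmp_path):
        ped, mp = self._write(
            tmp_path, ["f i 0 0 0 -9 A A"], ["1 a 0 100", "1 b 0 200"]
        )
        with pytest.raises(FileFormatError, match="fields"):
            read_ped_map(ped, mp)

    def test_non_integer_bp_raises(self, tmp_path):
        ped, mp = self._write(tmp_path, ["f i 0 0 0 -9 A A"], ["1 a 0 x1"])
        with pytest.raises(FileFormatError, match="non-integer bp"):
            read_ped_map(ped, mp)

    def test_three_alleles_raises_naming_marker(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            ["f1 i1 0 0 0 -9 A C", "f2 i2 0 0 0 -9 G G"],
            ["1 tri 0 100"],
        )
        with pytest.raises(DataError, match="tri"):
            read_ped_map(ped, mp)

    def test_empty_matrix_roundtrip(self, tmp_path):
        gm = GenotypeMatrix([], np.zeros((0, 2), np.int8), make_map({"1": 2}))
        write_ped_map(gm, tmp_path / "e.ped", tmp_path / "e.map")
        back = read_ped_map(tmp_path / "e.ped", tmp_path / "e.map")
        assert back.n_samples == 0 and back.n_markers == 2

    def test_het_writes_two_letters(self, tmp_path):
        gm = GenotypeMatrix(
            ["x"], np.array([[HET]], np.int8), make_map({"1": 1})
        )
        write_ped_map(gm, tmp_path / "h.ped", tmp_path / "h.map")
        fields = (tmp_path / "h.ped").read_text().split()
        assert fields[6] != fields[7]

    def test_random_roundtrip_identity(self, tmp_path, rng):
        gm = random_matrix(rng, 10, 100, n_chrom=2)
        # guarantee both alleles observed at every marker so the alphabetical
        # coding is recoverable from the written letters
        gm.codes[0, :] = HOM_A
        gm.codes[1, :] = HOM_B
        write_ped_map(gm, tmp_path / "r.ped", tmp_path / "r.map")
        back = read_ped_map(tmp_path / "r.ped", tmp_path / "r.map")
        assert back.equals(gm)

    @given(st.integers(0, 2**32 - 1))
    def test_roundtrip_is_idempotent(self, tmp_path_factory, seed):
        # write∘read is identity on anything read from disk, even when a
        # marker shows a single allele
        tmp = tmp_path_factory.mktemp("rt")
        rng = np.random.default_rng(seed)
        gm = random_matrix(rng, 4, 12)
        write_ped_map(gm, tmp / "a.ped", tmp / "a.map")
        first = read_ped_map(tmp / "a.ped", tmp / "a.map")
        write_ped_map(first, tmp / "b.ped", tmp / "b.map")
        second = read_ped_map(tmp / "b.ped", tmp / "b.map")
        assert second.equals(first)


class TestQCFilter:
    def test_sample_below_threshold_removed(self):
        # 94% call rate at a 95% threshold -> removed ("lower than 95%")
        markers = make_map({"1": 100})
        codes = np.zeros((2, 100), np.int8)
        codes[0, :6] = MISSING  # 94%
        codes[1, :5] = MISSING  # exactly 95% -> kept (strict inequality)
        gm = GenotypeMatrix(["bad", "edge"], codes, markers)
        out, report = qc_filter(gm, QCParams())
        assert report.removed_samples == ["bad"]
        assert out.sample_ids == ["edge"]

    def test_fully_observed_matrix_untouched(self, rng):
        gm = random_matrix(rng, 5, 50, p_missing=0.0)
        out, report = qc_filter(gm)
        assert out.equals(gm)
        assert not report.removed_samples and not report.removed_snps

    def test_removals_match_bruteforce_rates(self, rng):
        gm = random_matrix(rng, 10, 200, p_missing=0.08)
        params = QCParams(min_sample_call_rate=0.95, min_snp_call_rate=0.9)
        out, report = qc_filter(gm, params)
        # brute-force row rates on the full matrix
        exp_bad_samples = [
            gm.sample_ids[i]
            for i in range(gm.n_samples)
            if sum(gm.codes[i] != MISSING) / gm.n_markers < 0.95
        ]
        assert report.removed_samples == exp_bad_samples
        keep = [i for i, s in enumerate(gm.sample_ids) if s not in exp_bad_samples]
        exp_bad_snps = [
            gm.markers.snp_id[j]
            for j in range(gm.n_markers)
            if sum(gm.codes[i, j] != MISSING for i in keep) / len(keep) < 0.9
        ]
        assert report.removed_snps == exp_bad_snps

    def test_all_samples_removed_raises(self):
        gm = GenotypeMatrix(
            ["a"], np.full((1, 10), MISSING, np.int8), make_map({"1": 10})
        )
        with pytest.raises(EmptyResultError):
            qc_filter(gm)

    def test_idempotent(self, rng):
        gm = random_matrix(rng, 12, 150, p_missing=0.03)
        once, _ = qc_filter(gm)
        twice, rep = qc_filter(once)
        assert twice.equals(once)
        assert not rep.removed_samples and not rep.removed_snps

    def test_removing_missing_heavy_sample_raises_snp_call_rates(self, rng):
        # the monotonicity motivating the sample-first filter order: dropping
        # a sample never lowers the call rate of the SNPs it was missing at
        gm = random_matrix(rng, 8, 60, p_missing=0.2)
        base = gm.snp_call_rates()
        for i in range(gm.n_samples):
            reduced = gm.take_samples(np.array([k for k in range(8) if k != i]))
            missing_here = gm.codes[i] == MISSING
            assert (
                reduced.snp_call_rates()[missing_here] >= base[missing_here] - 1e-12
            ).all()


class TestSubsetAutosomes:
    def test_drops_sex_chromosome(self, rng):
        markers = MarkerMap.from_records(
            [("1", "a", 100), ("2", "b", 100), ("X", "c", 100)]
        )
        gm = GenotypeMatrix(["s"], np.zeros((1, 3), np.int8), markers)
        out = subset_autosomes(gm)
        assert list(out.markers.chromosome) == ["1", "2"]

    def test_identity_when_all_autosomal(self, rng):
        gm = random_matrix(rng, 3, 30, n_chrom=3)
        assert subset_autosomes(gm, {"1", "2", "3"}).equals(gm)

    def test_matches_set_filter(self, rng):
        records = [
            (c, f"{c}_{j}", (j + 1) * 1000)
            for c in ["1", "5", "18", "X", "Y"]
            for j in range(20)
        ]
        gm = GenotypeMatrix(
            ["s"], np.zeros((1, 100), np.int8), MarkerMap.from_records(records)
        )
        out = subset_autosomes(gm)
        expected = {c for c in out.markers.chromosome}
        assert expected == {"1", "5", "18"}
        assert out.n_markers == 60

    def test_empty_result_warns(self, rng):
        gm = random_matrix(rng, 2, 10)
        with pytest.warns(UserWarning):
            subset_autosomes(gm, {"99"})


class TestBedIntervals:
    def test_one_based_to_bed_conversion(self, tmp_path):
        # 1-based inclusive [135852700, 136018155] -> BED 135852699 136018155
        path = tmp_path / "i.bed"
        write_bed_intervals([("8", 135_852_700, 136_018_155)], path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split() == ["8", "135852699", "136018155", "."]

    def test_empty_writes_header_only(self, tmp_path):
        path = tmp_path / "e.bed"
        write_bed_intervals([], path)
        content = path.read_text().splitlines()
        assert len(content) == 1 and content[0].startswith("#")

    def test_start_after_end_raises(self, tmp_path):
        with pytest.raises(DataError):
            write_bed_intervals([("1", 10, 5)], tmp_path / "x.bed")

    def test_roundtrip_random_intervals(self, tmp_path, rng):
        ivs = []
        for _ in range(20):
            chrom = str(rng.integers(1, 19))
            start = int(rng.integers(1, 10**8))
            ivs.append((chrom, start, start + int(rng.integers(0, 10**6))))
        path = tmp_path / "r.bed"
        write_bed_intervals(ivs, path)
        back = read_bed_intervals(path)
        assert sorted(back) == sorted(ivs)
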