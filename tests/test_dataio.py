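"""Readers/writers, blocked streaming, the cube container, and PLINK import."""

import struct

import numpy as np
import pytest

from lmmscan import MemoryMeter, ResultCube, memory_budget
from lmmscan.dataio import (
    DimensionMismatchError,
    DuplicateIdError,
    NonNumericError,
    SampleAlignmentError,
    TruncatedFileError,
    export_cube_tsv,
    iter_blocks,
    read_cube,
    read_matrix,
    read_plink,
    validate_sample_order,
    write_cube,
    write_matrix_binary,
    write_matrix_tsv,
)


class TestMatrixRoundTrip:
    def test_tsv_round_trip(self, tmp_path, rng):
        values = rng.standard_normal((10, 4))
        rows = [f"S{i}" for i in range(10)]
        cols = [f"rs{j}" for j in range(4)]
        path = tmp_path / "m.tsv"
        write_matrix_tsv(path, values, rows, cols)
        got, got_rows, got_cols = read_matrix(path)
        np.testing.assert_allclose(got, values)
        assert got_rows == rows and got_cols == cols

    def test_binary_round_trip_bit_identical(self, tmp_path, rng):
        values = rng.standard_normal((100, 100))
        path = tmp_path / "m.mmg"
        write_matrix_binary(path, values)
        got, _, _ = read_matrix(path)
        assert got.tobytes() == values.tobytes()

    def test_missing_token_na(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_matrix_tsv(path, np.array([[1.0, np.nan]]), ["a"], ["x", "y"])
        assert "NA" in path.read_text()
        got, _, _ = read_matrix(path)
        assert np.isnan(got[0, 1])

    def test_out_of_range_dosage_warns_but_keeps(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_matrix_tsv(path, np.array([[3.5, 1.0]]), ["a"], ["x", "y"])
        with pytest.warns(UserWarning):
            got, _, _ = read_matrix(path, expected_role="genotype")
        assert got[0, 0] == 3.5

    def test_named_validation_errors(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("id\tx\ty\na\t1.0\toops\n")
        with pytest.raises(NonNumericError):
            read_matrix(bad)
        dup = tmp_path / "dup.tsv"
        dup.write_text("id\tx\tx\na\t1\t2\n")
        with pytest.raises(DuplicateIdError):
            read_matrix(dup)
        rect = tmp_path / "rect.tsv"
        write_matrix_tsv(rect, np.ones((2, 3)), ["a", "b"], ["x", "y", "z"])
        with pytest.raises(DimensionMismatchError):
            read_matrix(rect, expected_role="kinship")


class TestIterBlocks:
    def test_partition_sizes(self, rng):
        values = rng.standard_normal((4, 10))
        sizes = [b.shape[1] for _, b in iter_blocks(values, 3)]
        assert sizes == [3, 3, 3, 1]

    @pytest.mark.parametrize("fmt", ["array", "tsv", "mmg1"])
    def test_concatenation_recovers_matrix(self, tmp_path, rng, fmt):
        values = rng.standard_normal((6, 11))
        if fmt == "array":
            source = values
        elif fmt == "tsv":
            source = tmp_path / "m.tsv"
            write_matrix_tsv(source, values, [f"S{i}" for i in range(6)],
                             [f"C{j}" for j in range(11)])
        else:
            source = tmp_path / "m.mmg"
            write_matrix_binary(source, values)
        blocks = [b for _, b in iter_blocks(source, 4)]
        np.testing.assert_allclose(np.hstack(blocks), values)

    def test_labels_cover_columns_in_order(self, tmp_path, rng):
        values = rng.standard_normal((3, 5))
        path = tmp_path / "m.tsv"
        write_matrix_tsv(path, values, ["a", "b", "c"],
                         [f"rs{j}" for j in range(5)])
        labels = [lab for labs, _ in iter_blocks(path, 2) for lab in labs]
        assert labels == [f"rs{j}" for j in range(5)]

    def test_truncated_mmg1_names_offset(self, tmp_path, rng):
        path = tmp_path / "m.mmg"
        write_matrix_binary(path, rng.standard_normal((8, 8)))
        data = path.read_bytes()[:-16]
        path.write_bytes(data)
        with pytest.raises(TruncatedFileError, match=str(len(data))):
            list(iter_blocks(path, 3))

    def test_peak_entries_within_budget(self, tmp_path, rng):
        n, m, bc, p = 50, 200, 16, 3
        path = tmp_path / "g.mmg"
        write_matrix_binary(path, rng.standard_normal((n, m)))
        meter = MemoryMeter()
        for _ in iter_blocks(path, bc, meter=meter):
            pass
        assert meter.peak_entries <= memory_budget(n, p, bc + 1)


class TestCubeFile:
    def _cube(self, rng, m=4, t=2, p=3):
        B = rng.standard_normal((m, t, p))
        SE = np.abs(rng.standard_normal((m, t, p))) + 0.1
        CHI2 = np.abs(rng.standard_normal((m, t)))
        return ResultCube(B=B, SE=SE, CHI2=CHI2,
                          snp_ids=[f"rs{i}" for i in range(m)],
                          trait_ids=[f"T{j}" for j in range(t)],
                          coef_names=["intercept", "covar1", "snp"])

    def test_binary_round_trip_bit_identical(self, tmp_path, rng):
        cube = self._cube(rng)
        path = tmp_path / "out.bcub"
        write_cube(path, cube)
        got = read_cube(path)
        assert got.B.tobytes() == cube.B.tobytes()
        assert got.SE.tobytes() == cube.SE.tobytes()
        assert got.CHI2.tobytes() == cube.CHI2.tobytes()
        assert got.snp_ids == cube.snp_ids
        assert got.trait_ids == cube.trait_ids
        # writing the reread cube reproduces the file byte-for-byte
        path2 = tmp_path / "again.bcub"
        write_cube(path2, got)
        assert path2.read_bytes() == path.read_bytes()

    def test_tsv_export_long_format(self, tmp_path, rng):
        cube = self._cube(rng, m=4, t=2, p=3)
        cube.B[1, 0] = np.nan
        cube.SE[1, 0] = np.nan
        cube.CHI2[1, 0] = np.nan
        path = tmp_path / "out.tsv"
        export_cube_tsv(cube, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 + 4 * 2 * 3
        assert lines[0].split("\t") == ["snp_id", "trait_id", "coefficient",
                                        "beta", "se", "chi2", "pvalue"]
        nan_row = next(l for l in lines[1:] if l.startswith("rs1\tT0\tintercept"))
        assert "\tNA\t" in nan_row


class TestPlink:
    def test_round_trip_tiny_bed(self, tmp_path):
        # 5 samples, 2 SNPs; codes 00=hom A1 (2), 10=het (1), 11=hom A2 (0),
        # 01=missing
        prefix = tmp_path / "toy"
        (tmp_path / "toy.fam").write_text(
            "\n".join(f"F{i} I{i} 0 0 1 -9" for i in range(5)) + "\n")
        (tmp_path / "toy.bim").write_text(
            "1 rs1 0 100 A G\n1 rs2 0 200 C T\n")
        # SNP1 dosages (2,1,0,NA,2) -> codes 00,10,11,01 | 00
        # SNP2 dosages (0,0,1,1,1)  -> codes 11,11,10,10 | 10
        byte = lambda c: c[0] | (c[1] << 2) | (c[2] << 4) | (c[3] << 6)
        payload = bytes([0x6C, 0x1B, 0x01,
                         byte([0b00, 0b10, 0b11, 0b01]), byte([0b00, 0, 0, 0]),
                         byte([0b11, 0b11, 0b10, 0b10]), byte([0b10, 0, 0, 0])])
        (tmp_path / "toy.bed").write_bytes(payload)
        dosages, samples, snps = read_plink(prefix)
        assert samples == [f"I{i}" for i in range(5)]
        assert snps == ["rs1", "rs2"]
        np.testing.assert_array_equal(dosages[:, 1], [0, 0, 1, 1, 1])
        np.testing.assert_array_equal(dosages[[0, 1, 2, 4], 0], [2, 1, 0, 2])
        assert np.isnan(dosages[3, 0])


class TestSampleAlignment:
    def test_reorder_is_an_error_not_a_join(self):
        with pytest.raises(SampleAlignmentError):
            validate_sample_order(["a", "b", "c"], ["a", "c", "b"])
        validate_sample_order(["a", "b"], ["a", "b"], ["a", "b"])
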