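"""On-disk formats and the bounded-memory block iterator.

Reference formats are plain tab-delimited text (row = sample, header row of
column ids, first column = sample id, missing token "NA") and the MMG1 raw
binary matrix: magic ``MMG1``, three little-endian 64-bit unsigned integers
(rows, cols, element size), then row-major 64-bit floats.  Result cubes use
the BCUB container: magic, dimensions, label tables, then the B and SE
payloads followed by the chi-square grid.  A minimal PLINK .bed/.bim/.fam
reader is provided for dosage import (missing genotypes decode to NaN).

Sample alignment across files is by identifier with strict order equality:
a mismatch is always an error, never a silent reorder.
"""

from __future__ import annotations

import math
import struct
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .instrument import MemoryMeter
from .model import ResultCube

__all__ = [
    "DataValidationError",
    "DimensionMismatchError",
    "NonNumericError",
    "DuplicateIdError",
    "SampleAlignmentError",
    "TruncatedFileError",
    "read_matrix",
    "write_matrix_tsv",
    "write_matrix_binary",
    "iter_blocks",
    "write_cube",
    "read_cube",
    "export_cube_tsv",
    "read_plink",
    "validate_sample_order",
]

MISSING_TOKEN = "NA"
_MMG1_MAGIC = b"MMG1"
_BCUB_MAGIC = b"BCUB"
_MMG1_HEADER = struct.Struct("<4sQQQ")


class DataValidationError(ValueError):
    """Base class for malformed or inconsistent on-disk inputs."""


class DimensionMismatchError(DataValidationError):
    pass


class NonNumericError(DataValidationError):
    pass


class DuplicateIdError(DataValidationError):
    pass


class SampleAlignmentError(DataValidationError):
    pass


class TruncatedFileError(DataValidationError):
    pass


def _check_unique(labels: list[str], what: str, path) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateIdError(f"duplicate {what} id {lab!r} in {path}")
        seen.add(lab)


def _is_mmg1(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(4) == _MMG1_MAGIC


def read_matrix(path, expected_role: str | None = None):
    """Read a labelled matrix from TSV or MMG1 binary.

    Returns ``(values, row_ids, col_ids)``.  ``expected_role`` enables
    role-specific validation: ``"genotype"`` warns on dosages outside [0, 2]
    (imputation rounding can exceed the bounds; values are retained),
    ``"kinship"`` requires a square matrix.
    """
    path = Path(path)
    if _is_mmg1(path):
        values = _read_matrix_binary(path)
        row_ids = [f"R{i + 1}" for i in range(values.shape[0])]
        col_ids = [f"C{j + 1}" for j in range(values.shape[1])]
    else:
        with open(path) as fh:  # raw header: pandas would mangle duplicates
            raw_cols = fh.readline().rstrip("\n").split("\t")[1:]
        _check_unique(raw_cols, "column", path)
        try:
            frame = pd.read_csv(
                path, sep="\t", index_col=0,
                na_values=[MISSING_TOKEN], keep_default_na=False,
            )
        except pd.errors.ParserError as exc:
            raise DimensionMismatchError(f"ragged or malformed table {path}: {exc}") from exc
        try:
            values = frame.to_numpy(dtype=np.float64)
        except ValueError as exc:
            raise NonNumericError(f"non-numeric cell in {path}: {exc}") from exc
        row_ids = [str(i) for i in frame.index]
        col_ids = raw_cols
    _check_unique(row_ids, "row", path)
    _check_unique(col_ids, "column", path)
    if expected_role == "kinship" and values.shape[0] != values.shape[1]:
        raise DimensionMismatchError(
            f"kinship file {path} is {values.shape[0]}x{values.shape[1]}, not square"
        )
    if expected_role == "genotype":
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            warnings.warn(
                f"genotype dosages in {path} fall outside [0, 2]; retained as-is",
                UserWarning,
                stacklevel=2,
            )
    return values, row_ids, col_ids


def write_matrix_tsv(path, values: np.ndarray, row_ids, col_ids) -> None:
    values = np.atleast_2d(np.asarray(values))
    if values.shape != (len(row_ids), len(col_ids)):
        raise DimensionMismatchError(
            f"values {values.shape} vs labels ({len(row_ids)}, {len(col_ids)})"
        )
    frame = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="id")


def write_matrix_binary(path, values: np.ndarray) -> None:
    values = np.ascontiguousarray(np.atleast_2d(values), dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(_MMG1_HEADER.pack(_MMG1_MAGIC, values.shape[0], values.shape[1], 8))
        fh.write(values.tobytes(order="C"))


def _read_mmg1_header(path: Path) -> tuple[int, int]:
    size = path.stat().st_size
    if size < _MMG1_HEADER.size:
        raise TruncatedFileError(f"{path}: truncated header at byte offset {size}")
    with open(path, "rb") as fh:
        magic, rows, cols, elsize = _MMG1_HEADER.unpack(fh.read(_MMG1_HEADER.size))
    if magic != _MMG1_MAGIC:
        raise DataValidationError(f"{path}: bad magic {magic!r}")
    if elsize != 8:
        raise DataValidationError(f"{path}: unsupported element size {elsize}")
    expected = _MMG1_HEADER.size + 8 * rows * cols
    if size < expected:
        raise TruncatedFileError(
            f"{path}: payload ends at byte offset {size}, expected {expected}"
        )
    if size > expected:
        raise DimensionMismatchError(
            f"{path}: declared {rows}x{cols} but file has trailing bytes"
        )
    return rows, cols


def _read_matrix_binary(path: Path) -> np.ndarray:
    rows, cols = _read_mmg1_header(path)
    with open(path, "rb") as fh:
        fh.seek(_MMG1_HEADER.size)
        data = np.fromfile(fh, dtype="<f8", count=rows * cols)
    return data.reshape(rows, cols)


# ---------------------------------------------------------------------------
# Blocked column streaming
# ---------------------------------------------------------------------------

def iter_blocks(
    source,
    block_cols: int,
    meter: MemoryMeter | None = None,
    col_ids: list[str] | None = None,
) -> Iterator[tuple[list[str], np.ndarray]]:
    """Yield consecutive, non-overlapping column blocks covering the matrix.

    ``source`` is a TSV path, an MMG1 path, or an in-memory n x m array.
    Every column is delivered exactly once, in order, and no more than one
    block is resident at a time; each block registers its entry count with
    ``meter`` so the working-set bound can be asserted.  File sources never
    hold the full matrix in memory (MMG1 blocks are sliced from a memory
    map; TSV blocks are re-parsed per block via column selection).
    """
    if block_cols < 1:
        raise ValueError("block_cols must be >= 1")
    if isinstance(source, np.ndarray):
        yield from _iter_blocks_array(source, block_cols, meter, col_ids)
        return
    path = Path(source)
    if _is_mmg1(path):
        yield from _iter_blocks_mmg1(path, block_cols, meter)
    else:
        yield from _iter_blocks_tsv(path, block_cols, meter)


def _register(meter: MemoryMeter | None, block: np.ndarray):
    if meter is not None:
        meter.alloc("genotype_block", block.size)


def _iter_blocks_array(values, block_cols, meter, col_ids):
    m = values.shape[1]
    labels = col_ids if col_ids is not None else [f"C{j + 1}" for j in range(m)]
    for start in range(0, m, block_cols):
        stop = min(start + block_cols, m)
        block = np.array(values[:, start:stop], dtype=np.float64)
        _register(meter, block)
        yield labels[start:stop], block
    if meter is not None:
        meter.free("genotype_block")


def _iter_blocks_mmg1(path, block_cols, meter):
    rows, cols = _read_mmg1_header(path)
    mm = np.memmap(path, dtype="<f8", mode="r",
                   offset=_MMG1_HEADER.size, shape=(rows, cols))
    for start in range(0, cols, block_cols):
        stop = min(start + block_cols, cols)
        block = np.array(mm[:, start:stop], dtype=np.float64)
        _register(meter, block)
        yield [f"C{j + 1}" for j in range(start, stop)], block
    if meter is not None:
        meter.free("genotype_block")
    del mm


def _iter_blocks_tsv(path, block_cols, meter):
    header = pd.read_csv(path, sep="\t", nrows=0)
    n_cols = header.shape[1] - 1  # first column holds sample ids
    labels = [str(c) for c in header.columns[1:]]
    for start in range(0, n_cols, block_cols):
        stop = min(start + block_cols, n_cols)
        frame = pd.read_csv(
            path, sep="\t", usecols=[0] + list(range(start + 1, stop + 1)),
            index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False,
        )
        block = frame.to_numpy(dtype=np.float64)
        _register(meter, block)
        yield labels[start:stop], block
    if meter is not None:
        meter.free("genotype_block")


# ---------------------------------------------------------------------------
# Result cube container
# ---------------------------------------------------------------------------

def _pack_labels(labels: list[str]) -> bytes:
    payload = "\n".join(labels).encode("utf-8")
    return struct.pack("<Q", len(payload)) + payload


def _unpack_labels(fh) -> list[str]:
    (length,) = struct.unpack("<Q", fh.read(8))
    payload = fh.read(length).decode("utf-8")
    return payload.split("\n") if payload else []


def write_cube(path, cube: ResultCube) -> None:
    """Write the m x t x p result cube in the BCUB binary container."""
    m, t, p = cube.shape
    with open(path, "wb") as fh:
        fh.write(_BCUB_MAGIC)
        fh.write(struct.pack("<QQQ", m, t, p))
        fh.write(_pack_labels(cube.snp_ids))
        fh.write(_pack_labels(cube.trait_ids))
        fh.write(_pack_labels(cube.coef_names))
        fh.write(np.ascontiguousarray(cube.B, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(cube.SE, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(cube.CHI2, dtype="<f8").tobytes())


def read_cube(path) -> ResultCube:
    with open(path, "rb") as fh:
        if fh.read(4) != _BCUB_MAGIC:
            raise DataValidationError(f"{path}: not a BCUB cube file")
        m, t, p = struct.unpack("<QQQ", fh.read(24))
        snp_ids = _unpack_labels(fh)
        trait_ids = _unpack_labels(fh)
        coef_names = _unpack_labels(fh)
        need = 8 * (2 * m * t * p + m * t)
        payload = fh.read(need)
        if len(payload) < need:
            offset = path if isinstance(path, int) else Path(path).stat().st_size
            raise TruncatedFileError(
                f"{path}: cube payload ends at byte offset {offset}"
            )
    B = np.frombuffer(payload, dtype="<f8", count=m * t * p).reshape(m, t, p)
    SE = np.frombuffer(payload, dtype="<f8", count=m * t * p,
                       offset=8 * m * t * p).reshape(m, t, p)
    CHI2 = np.frombuffer(payload, dtype="<f8", count=m * t,
                         offset=16 * m * t * p).reshape(m, t)
    return ResultCube(B=B.copy(), SE=SE.copy(), CHI2=CHI2.copy(),
                      snp_ids=snp_ids, trait_ids=trait_ids, coef_names=coef_names)


def export_cube_tsv(cube: ResultCube, path) -> None:
    """Long-format TSV: one row per (SNP, trait, coefficient).

    The chi2/pvalue columns repeat the cell's SNP Wald test on every
    coefficient row of that cell; NaN (degenerate) cells export as "NA".
    """
    m, t, p = cube.shape
    pvals = cube.pvalues()
    rows = []
    for i in range(m):
        for j in range(t):
            for c in range(p):
                rows.append((
                    cube.snp_ids[i], cube.trait_ids[j], cube.coef_names[c],
                    cube.B[i, j, c], cube.SE[i, j, c],
                    cube.CHI2[i, j], pvals[i, j],
                ))
    frame = pd.DataFrame(
        rows, columns=["snp_id", "trait_id", "coefficient",
                       "beta", "se", "chi2", "pvalue"]
    )
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
                 float_format="%.6g")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam import
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major variant files
_BED_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])  # 2-bit code -> A1 dosage


def read_plink(prefix) -> tuple[np.ndarray, list[str], list[str]]:
    """Read PLINK .bed/.bim/.fam into an n x m dosage matrix (A1 counts).

    Missing genotypes decode to NaN.  Only the SNP-major .bed layout is
    supported.  Returns ``(dosages, sample_ids, snp_ids)``.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    sample_ids = [str(v) for v in fam.iloc[:, 1]]
    snp_ids = [str(v) for v in bim.iloc[:, 1]]
    n, m = len(sample_ids), len(snp_ids)
    bed_path = prefix.with_suffix(".bed")
    nb = math.ceil(n / 4)
    with open(bed_path, "rb") as fh:
        if fh.read(3) != _BED_MAGIC:
            raise DataValidationError(f"{bed_path}: not a SNP-major PLINK .bed file")
        raw = np.fromfile(fh, dtype=np.uint8)
    if raw.size < m * nb:
        raise TruncatedFileError(
            f"{bed_path}: payload ends at byte offset {3 + raw.size}, "
            f"expected {3 + m * nb}"
        )
    raw = raw[: m * nb].reshape(m, nb)
    codes = np.empty((m, nb * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (raw >> shift) & 0x3
    return _BED_DOSAGE[codes[:, :n]].T.copy(), sample_ids, snp_ids


def validate_sample_order(reference: Iterable[str], *others: Iterable[str]) -> None:
    """Require identical sample-id sequences across files; never reorder."""
    ref = list(reference)
    for k, ids in enumerate(others):
        ids = list(ids)
        if ids != ref:
            raise SampleAlignmentError(
                f"sample ids of input {k + 1} do not match the reference order "
                "(silent reordering is refused; align the files explicitly)"
            )
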