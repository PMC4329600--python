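"""Cholesky-whitening scan engine for single-trait analyses.

The trait covariance M is formed once, its lower Cholesky factor L computed
(L Lᵀ = M), and the covariates, trait, and every SNP column are whitened by
forward substitution.  Each whitened SNP test is then an ordinary least
squares problem; because the covariates are fixed across the scan, their
cross-products are computed once and every SNP costs only the 2p-1 new
cross-products involving its own column plus an O(p²) partitioned solve.

Per-SNP work after whitening is O(np); the scan's dominant cost is whitening
the m SNP columns at n²/2 multiply-adds each, i.e. O(m n²) per trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import dataio
from .instrument import (
    MemoryMeter,
    OpCounter,
    madds_cell_solve,
    madds_cholesky,
    madds_dot,
    madds_gemv,
    madds_syrk,
    madds_trsv,
)
from .model import (
    AssocRecord,
    CovarianceModel,
    DimensionError,
    FactorizationError,
    KinshipMatrix,
    ResultCube,
    VarianceEstimate,
    build_covariance,
    solve_partitioned_cell,
    wald_test,
)

__all__ = [
    "WhitenedScanState",
    "cholesky_covariance",
    "whiten",
    "build_scan_state",
    "scan_snp",
    "run_chol_gwas",
    "DEFAULT_BLOCK_COLS",
]

DEFAULT_BLOCK_COLS = 256


def cholesky_covariance(M: CovarianceModel | np.ndarray,
                        counter: OpCounter | None = None) -> np.ndarray:
    """Lower Cholesky factor L with L Lᵀ = M; fails with the pivot index."""
    Mv = M.M if isinstance(M, CovarianceModel) else np.asarray(M, dtype=np.float64)
    try:
        L = scipy.linalg.cholesky(Mv, lower=True)
    except scipy.linalg.LinAlgError as exc:
        pivot = None
        head = str(exc).split("-", 1)[0]
        if head.isdigit():
            pivot = int(head) - 1
        raise FactorizationError(
            f"covariance is not positive definite (failing pivot {pivot})",
            pivot=pivot,
        ) from exc
    if counter is not None:
        counter.add("cholesky", madds_cholesky(Mv.shape[0]))
        counter.call("cholesky")
    return L


def whiten(L: np.ndarray, A: np.ndarray, counter: OpCounter | None = None,
           phase: str = "whiten") -> np.ndarray:
    """Solve L W = A by forward substitution (L⁻¹ is never formed).

    Columns are processed one at a time so the result of a column never
    depends on which other columns share its block — scan output is
    bit-identical under any column blocking.
    """
    A = np.asarray(A, dtype=np.float64)
    vector = A.ndim == 1
    A2 = A.reshape(-1, 1) if vector else A
    n = L.shape[0]
    if A2.shape[0] != n:
        raise DimensionError(f"whiten: L is {L.shape} but A has {A2.shape[0]} rows")
    out = np.empty_like(A2)
    for j in range(A2.shape[1]):
        out[:, j] = scipy.linalg.solve_triangular(
            L, A2[:, j], lower=True, check_finite=False
        )
    if counter is not None:
        counter.add(phase, A2.shape[1] * madds_trsv(n))
        counter.call(f"{phase}_col", A2.shape[1])
    return out[:, 0] if vector else out


@dataclass
class WhitenedScanState:
    """Per-trait cache: whitened covariates/trait and their cross-products."""

    L: np.ndarray
    XL_w: np.ndarray
    y_w: np.ndarray
    SLL: np.ndarray          # XL_wᵀ XL_w
    sLy: np.ndarray          # XL_wᵀ y_w
    A_factor: tuple          # Cholesky factor of SLL
    g0: np.ndarray           # SLL⁻¹ sLy, the covariate-only GLS fit


def build_scan_state(L: np.ndarray, XL: np.ndarray, y: np.ndarray,
                     counter: OpCounter | None = None) -> WhitenedScanState:
    XL = np.atleast_2d(np.asarray(XL, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    XL_w = whiten(L, XL, counter, phase="whiten_covariates")
    y_w = whiten(L, y, counter, phase="whiten_covariates")
    SLL = XL_w.T @ XL_w
    sLy = XL_w.T @ y_w
    n, q = XL_w.shape
    if counter is not None:
        counter.add("covariate_cross", madds_syrk(n, q) + madds_gemv(n, q))
    try:
        A_factor = scipy.linalg.cho_factor(SLL, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise FactorizationError(
            "covariate cross-product matrix is singular (collinear covariates)"
        ) from exc
    g0 = scipy.linalg.cho_solve(A_factor, sLy)
    return WhitenedScanState(L=L, XL_w=XL_w, y_w=y_w, SLL=SLL, sLy=sLy,
                             A_factor=A_factor, g0=g0)


def scan_snp(state: WhitenedScanState, xr_w: np.ndarray,
             snp_id: str = "snp", trait_id: str = "trait",
             counter: OpCounter | None = None) -> AssocRecord:
    """Test one whitened SNP column, reusing all covariate cross-products.

    A SNP column collinear with the covariates (e.g. a monomorphic marker
    against an intercept) yields a degenerate NaN record rather than
    aborting the scan.
    """
    xr_w = np.asarray(xr_w, dtype=np.float64).ravel()
    n, q = state.XL_w.shape
    if xr_w.shape[0] != n:
        raise DimensionError("whitened SNP column has the wrong length")
    v = state.XL_w.T @ xr_w
    r = float(xr_w @ xr_w)
    s = float(xr_w @ state.y_w)
    if counter is not None:
        counter.add("scan", madds_gemv(n, q) + 2 * madds_dot(n) + madds_cell_solve(q))
    p = q + 1
    cell = solve_partitioned_cell(state.A_factor, state.g0, v, r, s)
    if cell is None:
        nan = np.full(p, np.nan)
        return AssocRecord(snp_id=snp_id, trait_id=trait_id, beta=nan,
                           se=nan.copy(), chi2=float("nan"),
                           pvalue=float("nan"), degenerate=True)
    beta, se, chi2 = cell
    _, pvalue = wald_test(float(beta[-1]), float(se[-1]))
    return AssocRecord(snp_id=snp_id, trait_id=trait_id, beta=beta, se=se,
                       chi2=chi2, pvalue=pvalue, degenerate=False)


def run_chol_gwas(
    genotypes,
    y: np.ndarray,
    XL: np.ndarray,
    phi: KinshipMatrix | np.ndarray,
    ve: VarianceEstimate,
    block_cols: int = DEFAULT_BLOCK_COLS,
    snp_ids: list[str] | None = None,
    trait_id: str = "trait",
    counter: OpCounter | None = None,
    meter: MemoryMeter | None = None,
) -> ResultCube:
    """Whiten-and-scan one trait over all SNPs; returns an m x 1 x p cube.

    ``genotypes`` may be an in-memory n x m dosage array or a path streamed
    through :func:`lmmscan.dataio.iter_blocks`; output is identical either
    way and independent of the block size.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    XL = np.atleast_2d(np.asarray(XL, dtype=np.float64))
    phi_values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi)
    n = phi_values.shape[0]
    if y.shape[0] != n or XL.shape[0] != n:
        raise DimensionError(
            f"sample counts disagree: kinship {n}, trait {y.shape[0]}, "
            f"covariates {XL.shape[0]}"
        )
    if isinstance(genotypes, np.ndarray) and genotypes.shape[0] != n:
        raise DimensionError(
            f"genotypes have {genotypes.shape[0]} samples, kinship has {n}"
        )
    M = build_covariance(phi_values, ve.sigma2, ve.h2)
    if meter is not None:
        meter.alloc("covariance", n * n)
    L = cholesky_covariance(M, counter)
    del M
    q = XL.shape[1]
    state = build_scan_state(L, XL, y, counter)
    if meter is not None:
        meter.alloc("whitened_covariates", n * q)
        meter.alloc("whitened_trait", n)

    records: list[AssocRecord] = []
    for labels, block in dataio.iter_blocks(genotypes, block_cols, meter=meter,
                                            col_ids=snp_ids):
        if block.shape[0] != n:
            raise DimensionError(
                f"genotype block has {block.shape[0]} samples, kinship has {n}"
            )
        block_w = whiten(L, block, counter, phase="whiten_snps")
        if meter is not None:  # whitened copy replaces the raw block
            meter.alloc("genotype_block", block_w.size)
        for j, label in enumerate(labels):
            records.append(scan_snp(state, block_w[:, j], snp_id=label,
                                    trait_id=trait_id, counter=counter))
    if meter is not None:
        for name in ("covariance", "whitened_covariates", "whitened_trait",
                     "genotype_block"):
            meter.free(name)

    m, p = len(records), q + 1
    B = np.empty((m, 1, p))
    SE = np.empty((m, 1, p))
    CHI2 = np.empty((m, 1))
    for i, rec in enumerate(records):
        B[i, 0] = rec.beta
        SE[i, 0] = rec.se
        CHI2[i, 0] = rec.chi2
    coef_names = [f"covar{j + 1}" for j in range(q)] + ["snp"]
    coef_names[0] = "intercept"
    return ResultCube(B=B, SE=SE, CHI2=CHI2,
                      snp_ids=[r.snp_id for r in records],
                      trait_ids=[trait_id], coef_names=coef_names)
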