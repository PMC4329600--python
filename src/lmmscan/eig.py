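"""Eigen-rotation scan engine for multi-trait (omics) analyses.

Three structural facts make the m x t association grid cheap: the kinship
matrix Phi is shared by every SNP and every trait; M = sigma²(h² Phi +
(1-h²) I) shares Phi's eigenvectors, with eigenvalues obtained by shifting
and scaling Phi's; and in the eigenbasis M is diagonal, so its inverse is a
vector of per-sample weights.  Hence Phi is eigendecomposed once, the
covariates, every SNP column and every trait column are rotated exactly
once, and each grid cell reduces to a weighted least-squares solve with that
trait's weights.

With b SNPs resident per block and all t traits resident, the working set is
n² + (b + t + p)·n entries; the grid-fill cost is O(m t n) once both m and t
exceed n, otherwise the O(n² (m + t)) rotations dominate.
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
    madds_dot,
    madds_gemv,
    madds_syrk,
)
from .model import (
    DimensionError,
    DomainError,
    KinshipMatrix,
    MissingDataError,
    ResultCube,
    SingularDesignError,
    VarianceEstimate,
    solve_partitioned_cell,
)
from .variance import EigenKinship, eigendecompose_kinship, shifted_eigenvalues

__all__ = [
    "WeightGrid",
    "rotate_matrix",
    "wls_solve",
    "run_eig_gwas",
    "count_operations",
    "DEFAULT_BLOCK_COLS",
]

DEFAULT_BLOCK_COLS = 256


@dataclass
class WeightGrid:
    """Per-trait inverse-variance weights in the eigenbasis.

    Trait j's weights are 1 / (sigma²_j (h²_j lambda_i + (1 - h²_j))),
    recomputed on demand from the shared eigenvalues (O(n) per trait) rather
    than cached for all traits at once.
    """

    ek: EigenKinship
    ves: list[VarianceEstimate]

    def weights(self, j: int) -> np.ndarray:
        ve = self.ves[j]
        d = shifted_eigenvalues(self.ek, ve.sigma2, ve.h2)
        w = 1.0 / d
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise DomainError(f"non-finite weight for trait {j}")
        return w


def rotate_matrix(ek: EigenKinship, A: np.ndarray,
                  counter: OpCounter | None = None,
                  phase: str = "rotate") -> np.ndarray:
    """Rotate columns into Phi's eigenbasis: returns Vᵀ A.

    Columns are rotated one at a time so each column's result is independent
    of the blocking, keeping scan output bit-identical for any block size.
    """
    A = np.asarray(A, dtype=np.float64)
    vector = A.ndim == 1
    A2 = A.reshape(-1, 1) if vector else A
    n = ek.n
    if A2.shape[0] != n:
        raise DimensionError(f"rotate: eigenbasis is {n}-dim but A has {A2.shape[0]} rows")
    Vt = ek.eigenvectors.T
    out = np.empty_like(A2)
    for j in range(A2.shape[1]):
        out[:, j] = Vt @ A2[:, j]
    if counter is not None:
        counter.add(phase, A2.shape[1] * madds_gemv(n, n))
        counter.call(f"{phase}_col", A2.shape[1])
    return out[:, 0] if vector else out


def wls_solve(X_rot: np.ndarray, y_rot: np.ndarray, w: np.ndarray,
              counter: OpCounter | None = None):
    """Weighted least squares: beta = (XᵀWX)⁻¹XᵀWy with W = diag(w).

    The coefficient covariance is (XᵀWX)⁻¹ (two-step convention: the weights
    already carry the step-one variance estimate).  Returns
    ``(beta, se, cov)``.
    """
    X_rot = np.atleast_2d(np.asarray(X_rot, dtype=np.float64))
    y_rot = np.asarray(y_rot, dtype=np.float64).ravel()
    w = np.asarray(w, dtype=np.float64).ravel()
    n, p = X_rot.shape
    if y_rot.shape[0] != n or w.shape[0] != n:
        raise DimensionError("wls_solve inputs disagree on the sample count")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DomainError("weights must be finite and positive")
    sw = np.sqrt(w)
    Xs = X_rot * sw[:, None]
    ys = y_rot * sw
    Q, R = np.linalg.qr(Xs)
    tol = 1e-10 * float(np.max(np.linalg.norm(Xs, axis=0)))
    small = np.abs(np.diag(R)) <= tol
    if np.any(small):
        raise SingularDesignError(
            f"design column {int(np.argmax(small))} is collinear after weighting",
            column=int(np.argmax(small)),
        )
    beta = scipy.linalg.solve_triangular(R, Q.T @ ys, lower=False)
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p), lower=False)
    cov = Rinv @ Rinv.T
    se = np.sqrt(np.diag(cov))
    if counter is not None:
        counter.add("wls", madds_syrk(n, p) + madds_gemv(n, p) + p ** 3 / 3.0)
    return beta, se, cov


def run_eig_gwas(
    genotypes,
    phenotypes: np.ndarray,
    XL: np.ndarray,
    phi: KinshipMatrix | np.ndarray,
    ves: list[VarianceEstimate],
    block_cols: int = DEFAULT_BLOCK_COLS,
    snp_ids: list[str] | None = None,
    trait_ids: list[str] | None = None,
    counter: OpCounter | None = None,
    meter: MemoryMeter | None = None,
) -> ResultCube:
    """Fill the full m x t x p association grid; Phi is decomposed once.

    The covariates and every trait column are rotated exactly once up front;
    each genotype block is rotated exactly once as it streams through.
    Within a block the loop is trait-major: trait j's weights and weighted
    covariate cross-products are rebuilt (O(n p²)), then every resident SNP
    column costs the 2p-1 cross-products of a weighted cell solve.

    Degenerate cells (SNP collinear with the covariates under that trait's
    weights) are flagged NaN and the scan continues.
    """
    phenotypes = np.atleast_2d(np.asarray(phenotypes, dtype=np.float64))
    if phenotypes.ndim != 2:
        raise DimensionError("phenotypes must be an n x t matrix")
    XL = np.atleast_2d(np.asarray(XL, dtype=np.float64))
    phi_values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi)
    n = phi_values.shape[0]
    t = phenotypes.shape[1]
    if phenotypes.shape[0] != n or XL.shape[0] != n:
        raise DimensionError(
            f"sample counts disagree: kinship {n}, phenotypes "
            f"{phenotypes.shape[0]}, covariates {XL.shape[0]}"
        )
    if isinstance(genotypes, np.ndarray) and genotypes.shape[0] != n:
        raise DimensionError(
            f"genotypes have {genotypes.shape[0]} samples, kinship has {n}"
        )
    if np.any(~np.isfinite(phenotypes)):
        raise MissingDataError(
            "phenotypes contain missing values; complete data are assumed "
            "(apply mean_impute first)"
        )
    if len(ves) != t:
        raise DimensionError(f"{len(ves)} variance estimates for {t} traits")

    ek = eigendecompose_kinship(phi_values, counter=counter)
    if meter is not None:
        meter.alloc("eigenvectors", n * n)
    q = XL.shape[1]
    XL_rot = rotate_matrix(ek, XL, counter, phase="rotate_covariates")
    Y_rot = rotate_matrix(ek, phenotypes, counter, phase="rotate_traits")
    if meter is not None:
        meter.alloc("rotated_covariates", n * q)
        meter.alloc("rotated_traits", n * t)
    grid = WeightGrid(ek=ek, ves=list(ves))
    trait_ids = list(trait_ids) if trait_ids is not None else [
        f"T{j + 1}" for j in range(t)
    ]

    p = q + 1
    blocks_out: list[tuple[list[str], np.ndarray, np.ndarray, np.ndarray]] = []
    for labels, block in dataio.iter_blocks(genotypes, block_cols, meter=meter,
                                            col_ids=snp_ids):
        if block.shape[0] != n:
            raise DimensionError(
                f"genotype block has {block.shape[0]} samples, kinship has {n}"
            )
        block_rot = rotate_matrix(ek, block, counter, phase="rotate_snps")
        if meter is not None:  # rotated copy replaces the raw block
            meter.alloc("genotype_block", block_rot.size)
        b = block_rot.shape[1]
        Bb = np.empty((b, t, p))
        SEb = np.empty((b, t, p))
        C2b = np.empty((b, t))
        for j in range(t):
            w = grid.weights(j)
            sw = np.sqrt(w)
            XLs = XL_rot * sw[:, None]
            ys = Y_rot[:, j] * sw
            A = XLs.T @ XLs
            c = XLs.T @ ys
            if counter is not None:
                counter.add("wls", madds_dot(n) + q * madds_dot(n)
                            + madds_syrk(n, q) + madds_gemv(n, q))
            try:
                A_factor = scipy.linalg.cho_factor(A, lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise SingularDesignError(
                    "covariates are collinear under the trait weights"
                ) from exc
            g0 = scipy.linalg.cho_solve(A_factor, c)
            for i in range(b):
                xs = block_rot[:, i] * sw
                v = XLs.T @ xs
                r = float(xs @ xs)
                s = float(xs @ ys)
                if counter is not None:
                    counter.add("wls", madds_dot(n) + madds_gemv(n, q)
                                + 2 * madds_dot(n) + madds_cell_solve(q))
                cell = solve_partitioned_cell(A_factor, g0, v, r, s)
                if cell is None:
                    Bb[i, j] = np.nan
                    SEb[i, j] = np.nan
                    C2b[i, j] = np.nan
                else:
                    Bb[i, j], SEb[i, j], C2b[i, j] = cell
        blocks_out.append((labels, Bb, SEb, C2b))
    if meter is not None:
        for name in ("eigenvectors", "rotated_covariates", "rotated_traits",
                     "genotype_block"):
            meter.free(name)

    all_labels = [lab for labels, *_ in blocks_out for lab in labels]
    B = np.concatenate([b for _, b, _, _ in blocks_out], axis=0) if blocks_out \
        else np.empty((0, t, p))
    SE = np.concatenate([s for _, _, s, _ in blocks_out], axis=0) if blocks_out \
        else np.empty((0, t, p))
    CHI2 = np.concatenate([c for _, _, _, c in blocks_out], axis=0) if blocks_out \
        else np.empty((0, t))
    coef_names = [f"covar{j + 1}" for j in range(q)] + ["snp"]
    coef_names[0] = "intercept"
    return ResultCube(B=B, SE=SE, CHI2=CHI2, snp_ids=all_labels,
                      trait_ids=trait_ids, coef_names=coef_names)


def count_operations(n: int, m: int, t: int, p: int,
                     seed: int = 0) -> dict[str, float]:
    """Counted multiply-add totals per phase from an instrumented grid run.

    Generates a synthetic dataset of the requested size, runs the
    eigen-rotation engine with the operation counter attached, and returns
    the per-phase totals (``rotate_snps``, ``rotate_traits``, ``wls``,
    ``eigendecomposition``, ``total``).  Counts are of actually dispatched
    kernels, not closed-form models; t = 0 short-circuits to zero work.
    """
    if min(n, m, p) < 1 or t < 0:
        raise DomainError("sizes must be positive (t may be 0)")
    phases = ["eigendecomposition", "rotate_covariates", "rotate_traits",
              "rotate_snps", "wls"]
    if t == 0:
        counts = {ph: 0.0 for ph in phases}
        counts["total"] = 0.0
        return counts
    from . import synth  # local import: synth is a consumer-level module

    config = synth.SimConfig(n=n, m=m, t=t, p=p, seed=seed)
    phi, genotypes, XL, Y, _ = synth.simulate_dataset(config)
    ves = [VarianceEstimate(sigma2=1.0, h2=0.5) for _ in range(t)]
    counter = OpCounter()
    run_eig_gwas(genotypes, Y, XL, phi, ves, counter=counter)
    counts = {ph: float(counter.madds.get(ph, 0.0)) for ph in phases}
    counts["total"] = counter.total()
    return counts
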