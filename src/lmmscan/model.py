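"""Core model types and reference statistics for two-step mixed-model GWAS.

The linear mixed model treats a quantitative trait y over n samples as

    y = X beta + g + e,    g ~ N(0, sigma² h² Phi),   e ~ N(0, sigma² (1-h²) I)

where Phi is the kinship (relationship) matrix, h² the narrow-sense
heritability and sigma² the total trait variance.  Marginally
y ~ N(X beta, M) with M = sigma² (h² Phi + (1-h²) I), so per-SNP fixed
effects are generalized least-squares estimates

    b = (Xᵀ M⁻¹ X)⁻¹ Xᵀ M⁻¹ y .

This module owns the domain types, the dense-M GLS solver that serves as the
correctness oracle for the fast scan engines, and the scan-level statistics:
the Wald test, the genomic-control inflation factor lambda, and the
Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

__all__ = [
    "DimensionError",
    "DomainError",
    "FactorizationError",
    "MissingDataError",
    "SingularDesignError",
    "KinshipMatrix",
    "VarianceEstimate",
    "CovarianceModel",
    "DesignSplit",
    "AssocRecord",
    "ResultCube",
    "build_covariance",
    "gls_solve",
    "wald_test",
    "gc_lambda",
    "bonferroni_threshold",
    "CHI2_1_MEDIAN",
]

# Median of the chi-square distribution with 1 df; the null reference for
# genomic control.
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))

#: Relative pivot tolerance for rank-deficiency detection, applied to the
#: largest column norm of the (whitened) design.
RANK_TOL: float = 1e-10

#: Text output precision (significant digits) for exported tables.
TEXT_SIGNIFICANT_DIGITS: int = 6


class DimensionError(ValueError):
    """Shapes of the inputs are inconsistent."""


class DomainError(ValueError):
    """A parameter lies outside its mathematically valid domain."""


class FactorizationError(np.linalg.LinAlgError):
    """A required matrix factorization failed (e.g. non-PD covariance)."""

    def __init__(self, message: str, pivot: int | None = None):
        super().__init__(message)
        self.pivot = pivot


class SingularDesignError(np.linalg.LinAlgError):
    """The fixed-effect design is rank deficient."""

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


class MissingDataError(ValueError):
    """Missing values where the method assumes complete data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix Phi with ordered sample identifiers."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = list(self.sample_ids)
        n, m = self.values.shape if self.values.ndim == 2 else (0, -1)
        if self.values.ndim != 2 or n != m:
            raise DimensionError("kinship matrix must be square")
        if len(self.sample_ids) != n:
            raise DimensionError(
                f"kinship has {n} rows but {len(self.sample_ids)} sample ids"
            )
        scale = max(1.0, float(np.max(np.abs(self.values))) if n else 1.0)
        if n and float(np.max(np.abs(self.values - self.values.T))) > 1e-12 * scale:
            raise DomainError("kinship matrix is not symmetric (tolerance 1e-12)")
        if n and float(np.min(np.diag(self.values))) <= 0.0:
            raise DomainError("kinship diagonal entries must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceEstimate:
    """Per-trait variance components fixed after step one of the two-step fit.

    ``n_iter`` records the number of profile-likelihood evaluations spent by
    the optimizer (the quantity usually called v in cost models of the
    two-step method).
    """

    sigma2: float
    h2: float
    n_iter: int = 1
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise DomainError(f"sigma2 must be positive, got {self.sigma2}")
        if not (0.0 <= self.h2 < 1.0):
            raise DomainError(f"h2 must lie in [0, 1), got {self.h2}")
        if self.n_iter < 1:
            raise DomainError("n_iter must be >= 1")


@dataclass
class CovarianceModel:
    """Dense trait covariance M = sigma² (h² Phi + (1-h²) I)."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise DimensionError("covariance M must be square")

    @property
    def n(self) -> int:
        return self.M.shape[0]


@dataclass
class DesignSplit:
    """Fixed-effect design X = [X_L | X_R].

    X_L holds the p-1 covariate columns (intercept included) shared by every
    SNP test; X_R is the single per-SNP dosage column.
    """

    XL: np.ndarray
    XR: np.ndarray
    p: int = field(init=False)

    def __post_init__(self) -> None:
        self.XL = np.atleast_2d(np.asarray(self.XL, dtype=np.float64))
        self.XR = np.asarray(self.XR, dtype=np.float64).reshape(-1, 1)
        if self.XL.shape[0] != self.XR.shape[0]:
            raise DimensionError("XL and XR disagree on the sample count")
        if np.linalg.matrix_rank(self.XL) < self.XL.shape[1]:
            raise SingularDesignError("covariate matrix XL is rank deficient")
        self.p = self.XL.shape[1] + 1

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.XL, self.XR])


@dataclass
class AssocRecord:
    """One cell of the association grid: a single (SNP, trait) GLS fit."""

    snp_id: str
    trait_id: str
    beta: np.ndarray
    se: np.ndarray
    chi2: float
    pvalue: float
    degenerate: bool = False


@dataclass
class ResultCube:
    """The m x t x p cube of effect estimates with standard errors.

    ``B[i, j, :]`` and ``SE[i, j, :]`` hold the full coefficient vector and
    its standard errors for SNP i against trait j; ``CHI2[i, j]`` is the Wald
    statistic of the SNP coefficient (the last coefficient by convention).
    """

    B: np.ndarray
    SE: np.ndarray
    CHI2: np.ndarray
    snp_ids: list[str]
    trait_ids: list[str]
    coef_names: list[str]

    def __post_init__(self) -> None:
        self.B = np.ascontiguousarray(self.B, dtype=np.float64)
        self.SE = np.ascontiguousarray(self.SE, dtype=np.float64)
        self.CHI2 = np.ascontiguousarray(self.CHI2, dtype=np.float64)
        m, t, p = self.B.shape
        if self.SE.shape != (m, t, p) or self.CHI2.shape != (m, t):
            raise DimensionError("result cube arrays disagree on shape")
        if (len(self.snp_ids), len(self.trait_ids), len(self.coef_names)) != (m, t, p):
            raise DimensionError("result cube labels disagree with array shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.B.shape

    def pvalues(self) -> np.ndarray:
        """Two-sided p-values of the SNP Wald statistics (m x t)."""
        return stats.chi2.sf(self.CHI2, df=1)

    def record(self, i: int, j: int) -> AssocRecord:
        chi2 = float(self.CHI2[i, j])
        return AssocRecord(
            snp_id=self.snp_ids[i],
            trait_id=self.trait_ids[j],
            beta=self.B[i, j].copy(),
            se=self.SE[i, j].copy(),
            chi2=chi2,
            pvalue=float(stats.chi2.sf(chi2, df=1)),
            degenerate=bool(np.isnan(chi2)),
        )


# ---------------------------------------------------------------------------
# Covariance construction and the GLS oracle
# ---------------------------------------------------------------------------

def build_covariance(phi: KinshipMatrix | np.ndarray, sigma2: float, h2: float) -> CovarianceModel:
    """Form M = sigma² (h² Phi + (1-h²) I)."""
    values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DimensionError("kinship matrix must be square")
    if not (0.0 <= h2 < 1.0):
        raise DomainError(f"h2 must lie in [0, 1), got {h2}")
    if not sigma2 > 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    n = values.shape[0]
    M = sigma2 * (h2 * values + (1.0 - h2) * np.eye(n))
    return CovarianceModel(M=M)


def _cholesky_pd(M: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, raising FactorizationError with the pivot."""
    try:
        return scipy.linalg.cholesky(M, lower=True)
    except scipy.linalg.LinAlgError as exc:
        pivot = None
        msg = str(exc)
        head = msg.split("-", 1)[0]
        if head.isdigit():
            pivot = int(head) - 1  # LAPACK reports 1-based minors
        raise FactorizationError(
            f"covariance is not positive definite (failing pivot {pivot}): {msg}",
            pivot=pivot,
        ) from exc


def gls_solve(
    X: np.ndarray,
    y: np.ndarray,
    M: CovarianceModel | np.ndarray,
    rescale_residual: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generalized least squares: b = (XᵀM⁻¹X)⁻¹ XᵀM⁻¹y via factorization.

    The dense reference implementation both fast engines must reproduce.
    M is never inverted explicitly: it is Cholesky-factored and the design is
    whitened by triangular solves.

    By default the coefficient covariance is reported as (XᵀM⁻¹X)⁻¹ with M
    already carrying the step-one variance estimate — the two-step
    convention.  ``rescale_residual=True`` additionally multiplies by the
    whitened residual mean square (RSS / (n - p)).

    Returns
    -------
    beta, se, cov : the coefficient vector, its standard errors, and the
        p x p coefficient covariance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    Mv = M.M if isinstance(M, CovarianceModel) else np.asarray(M, dtype=np.float64)
    n, p = X.shape
    if y.shape[0] != n or Mv.shape != (n, n):
        raise DimensionError(
            f"inconsistent shapes: X {X.shape}, y {y.shape}, M {Mv.shape}"
        )
    L = _cholesky_pd(Mv)
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)

    Q, R = np.linalg.qr(Xw)
    col_norms = np.linalg.norm(Xw, axis=0)
    tol = RANK_TOL * float(np.max(col_norms)) if p else 0.0
    small = np.abs(np.diag(R)) <= tol
    if np.any(small):
        col = int(np.argmax(small))
        raise SingularDesignError(
            f"design column {col} is collinear with the preceding columns",
            column=col,
        )
    beta = scipy.linalg.solve_triangular(R, Q.T @ yw, lower=False)
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p), lower=False)
    cov = Rinv @ Rinv.T
    if rescale_residual:
        if n <= p:
            raise DomainError("residual rescaling needs n > p")
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        cov = cov * (rss / (n - p))
    se = np.sqrt(np.diag(cov))
    return beta, se, cov


# ---------------------------------------------------------------------------
# Shared partitioned normal-equation cell solver
# ---------------------------------------------------------------------------

def solve_partitioned_cell(
    A_factor: tuple[np.ndarray, bool],
    g0: np.ndarray,
    v: np.ndarray,
    r: float,
    s: float,
    pivot_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Solve a p x p GLS cell given cached covariate-only cross-products.

    The normal equations are partitioned as ``[[A, v], [vᵀ, r]] b = [c, s]``
    where A = X_LᵀWX_L and g0 = A⁻¹c are shared across the scan and only the
    2p-1 cross-products involving the SNP column (v, r, s) are new.  Returns
    ``(beta, se, chi2)`` or None when the SNP column is numerically collinear
    with the covariates (Schur pivot below ``pivot_tol`` relative to r).
    """
    u = scipy.linalg.cho_solve(A_factor, v, check_finite=False)
    schur = r - float(v @ u)
    if not np.isfinite(schur) or schur <= pivot_tol * max(r, np.finfo(float).tiny):
        return None
    gamma = (s - float(v @ g0)) / schur
    beta_L = g0 - u * gamma
    q = v.shape[0]
    # coefficient covariance blocks from the partitioned inverse
    Ainv_diag = np.diag(
        scipy.linalg.cho_solve(A_factor, np.eye(q), check_finite=False)
    )
    var_L = Ainv_diag + u * u / schur
    var_snp = 1.0 / schur
    beta = np.concatenate([beta_L, [gamma]])
    se = np.sqrt(np.concatenate([var_L, [var_snp]]))
    chi2 = (gamma / se[-1]) ** 2
    return beta, se, float(chi2)


# ---------------------------------------------------------------------------
# Scan-level statistics
# ---------------------------------------------------------------------------

def wald_test(beta_snp: float, se_snp: float) -> tuple[float, float]:
    """Two-sided Wald test of a single coefficient via chi-square with 1 df."""
    if not se_snp > 0:
        raise DomainError(f"standard error must be positive, got {se_snp}")
    chi2 = (beta_snp / se_snp) ** 2
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def gc_lambda(chi2_values) -> float:
    """Genomic-control inflation factor: median chi² over the chi²₁ median.

    Values near 1 indicate calibrated association tests; lambda > 1 signals
    residual stratification or other inflation.
    """
    values = np.asarray(chi2_values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DomainError("gc_lambda needs at least one statistic")
    if np.any(values < 0) or np.any(np.isnan(values)):
        raise DomainError("chi-square statistics must be non-negative")
    return float(np.median(values) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests
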