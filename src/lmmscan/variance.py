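"""Step one of the two-step method: per-trait estimation of (sigma², h²).

The kinship matrix Phi is eigendecomposed once, Phi = V Lambda Vᵀ.  Because
M = sigma² (h² Phi + (1-h²) I) shares Phi's eigenvectors, rotating the data
by Vᵀ diagonalizes M for every candidate h²: the rotated model is a weighted
least-squares problem with per-sample weights 1/w_i, w_i = h² lambda_i +
(1 - h²).  The total variance sigma² profiles out in closed form, leaving a
one-dimensional likelihood in h² that is maximized by a coarse grid followed
by bounded scalar refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .instrument import OpCounter, madds_eigh, madds_gemv
from .model import (
    DimensionError,
    DomainError,
    KinshipMatrix,
    MissingDataError,
    VarianceEstimate,
)

__all__ = [
    "EigenKinship",
    "RotatedData",
    "eigendecompose_kinship",
    "shifted_eigenvalues",
    "profile_loglik",
    "estimate_h2",
    "H2_UPPER",
]

#: Upper bound of the h² search; keeps every weight strictly positive even
#: when Phi has zero eigenvalues.
H2_UPPER: float = 1.0 - 1e-6

#: Grid points of the coarse h² sweep preceding refinement.
H2_GRID_POINTS: int = 21

#: Loglik ties within this tolerance resolve to the smallest h².
_TIE_TOL: float = 1e-9


@dataclass
class EigenKinship:
    """One-time spectral decomposition of Phi, reused by every trait.

    ``eigenvalues`` are sorted descending and clipped below at zero;
    ``eigenvectors`` columns match that order, Phi = V Lambda Vᵀ.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class RotatedData:
    """Trait and covariates rotated into Phi's eigenbasis."""

    y_rot: np.ndarray
    XL_rot: np.ndarray


def eigendecompose_kinship(
    phi: KinshipMatrix | np.ndarray, counter: OpCounter | None = None
) -> EigenKinship:
    """Eigendecompose Phi once; negative eigenvalues are clipped to zero.

    Eigenvalues below -1e-8 times the largest eigenvalue trigger a warning
    (empirical kinships are only near-PSD); smaller negative round-off is
    clipped silently.
    """
    values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DimensionError("kinship matrix must be square")
    scale = max(1.0, float(np.max(np.abs(values))))
    if float(np.max(np.abs(values - values.T))) > 1e-8 * scale:
        raise DomainError("kinship matrix is asymmetric beyond 1e-8")
    lam, V = scipy.linalg.eigh((values + values.T) / 2.0)
    lam, V = lam[::-1].copy(), V[:, ::-1].copy()
    lam_max = float(lam[0]) if lam.size else 0.0
    if lam.size and float(lam[-1]) < -1e-8 * max(lam_max, 1.0):
        warnings.warn(
            f"kinship has eigenvalues as low as {lam[-1]:.3e}; clipping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    np.clip(lam, 0.0, None, out=lam)
    if counter is not None:
        counter.add("eigendecomposition", madds_eigh(values.shape[0]))
        counter.call("eigendecompose")
    return EigenKinship(eigenvalues=lam, eigenvectors=V)


def shifted_eigenvalues(ek: EigenKinship, sigma2: float, h2: float) -> np.ndarray:
    """Eigenvalues of M obtained by shifting and scaling those of Phi.

    d_i = sigma² (h² lambda_i + (1 - h²)); strictly positive on the admitted
    parameter domain.
    """
    if not (0.0 <= h2 < 1.0):
        raise DomainError(f"h2 must lie in [0, 1), got {h2}")
    if not sigma2 > 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    return sigma2 * (h2 * ek.eigenvalues + (1.0 - h2))


def profile_loglik(
    h2: float,
    y_rot: np.ndarray,
    XL_rot: np.ndarray,
    eigenvalues: np.ndarray,
    reml: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Profiled Gaussian log-likelihood of the rotated null model at h².

    With weights w_i = h² lambda_i + (1 - h²) the covariate fit is weighted
    least squares; sigma² profiles to the weighted residual mean square and
    the returned value is the maximized log-likelihood at this h².

    Returns ``(loglik, sigma2_hat, beta_hat)``.
    """
    y_rot = np.asarray(y_rot, dtype=np.float64).ravel()
    XL_rot = np.atleast_2d(np.asarray(XL_rot, dtype=np.float64))
    lam = np.asarray(eigenvalues, dtype=np.float64).ravel()
    n, q = XL_rot.shape
    if y_rot.shape[0] != n or lam.shape[0] != n:
        raise DimensionError("rotated inputs disagree on the sample count")
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0.0):
        raise DomainError(f"non-positive variance weight at h2={h2}")
    sw = 1.0 / np.sqrt(w)
    Xs = XL_rot * sw[:, None]
    ys = y_rot * sw
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    logdet_w = float(np.sum(np.log(w)))
    if reml:
        dof = n - q
        sigma2 = rss / dof
        _, logdet_xtx = np.linalg.slogdet(Xs.T @ Xs)
        loglik = -0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet_w + logdet_xtx + dof)
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_w + n)
    return float(loglik), float(sigma2), beta


def estimate_h2(
    y: np.ndarray,
    XL: np.ndarray,
    ek: EigenKinship,
    reml: bool = False,
    counter: OpCounter | None = None,
) -> VarianceEstimate:
    """Maximize the profiled likelihood over h² in [0, 1) for one trait.

    A coarse grid of 21 points locates the mode's basin; bounded scalar
    minimization refines it to 1e-6.  Flat likelihoods (e.g. Phi = I, where
    h² is unidentifiable) tie-break to the smallest h² attaining the
    maximum.  ``n_iter`` reports the total number of likelihood evaluations
    (at most ~55 per trait).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    XL = np.atleast_2d(np.asarray(XL, dtype=np.float64))
    if y.shape[0] != ek.n or XL.shape[0] != ek.n:
        raise DimensionError("trait/covariates disagree with the kinship size")
    if np.any(~np.isfinite(y)):
        raise MissingDataError(
            "trait contains missing values; complete data are assumed "
            "(apply mean_impute first)"
        )
    if float(np.var(y)) <= 0.0:
        raise DomainError("zero-variance trait: h2 is undefined")

    V = ek.eigenvectors
    y_rot = V.T @ y
    XL_rot = V.T @ XL
    if counter is not None:
        counter.add("rotate_traits", madds_gemv(ek.n, ek.n))
        counter.add("rotate_covariates", XL.shape[1] * madds_gemv(ek.n, ek.n))

    evaluations = 0

    def objective(h2: float) -> float:
        nonlocal evaluations
        evaluations += 1
        ll, _, _ = profile_loglik(h2, y_rot, XL_rot, ek.eigenvalues, reml=reml)
        return ll

    grid = np.linspace(0.0, H2_UPPER, H2_GRID_POINTS)
    grid_ll = np.array([objective(h) for h in grid])
    i_best = int(np.argmax(grid_ll))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]

    candidates = list(zip(grid, grid_ll))
    if hi > lo:
        res = minimize_scalar(
            lambda h: -objective(h),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6, "maxiter": 30},
        )
        candidates.append((float(res.x), float(-res.fun)))

    best_ll = max(ll for _, ll in candidates)
    h2_hat = min(h for h, ll in candidates if ll >= best_ll - _TIE_TOL)
    loglik, sigma2_hat, _ = profile_loglik(h2_hat, y_rot, XL_rot, ek.eigenvalues, reml=reml)
    return VarianceEstimate(
        sigma2=sigma2_hat, h2=float(h2_hat), n_iter=evaluations, loglik=loglik
    )
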