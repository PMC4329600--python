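"""Synthetic cohorts with known ground truth for the mixed-model scan.

The generator emulates the study design the two-step method targets: a
family-structured kinship matrix, independent biallelic dosages, and
phenotypes drawn from the generative model

    y = X_L beta_L + sum_c x_c gamma_c + g + e,
    g ~ N(0, sigma² h² Phi),   e ~ N(0, sigma² (1 - h²) I),

plus the metabolomics-style expansion of base measurements into all
pair-wise ratio traits, mean imputation of sporadically missing values, and
a genotype-derived genomic relationship matrix for cohorts without a
pedigree.

All randomness flows from a single seed through per-component substreams
(genotypes, covariates, per-trait genetic and environmental draws), so e.g.
adding traits never perturbs the genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import DimensionError, DomainError, KinshipMatrix

__all__ = [
    "SimConfig",
    "simulate_kinship",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_dataset",
    "ratio_traits",
    "mean_impute",
    "genomic_kinship",
]

# substream component indices under the master seed
_GENOTYPES, _COVARIATES, _GENETIC, _ENVIRONMENT = 0, 1, 2, 3


@dataclass
class SimConfig:
    """Study design of a synthetic cohort.

    ``h2`` and ``sigma2`` may be scalars (shared by all traits) or length-t
    sequences; ``causal`` maps SNP column indices to fixed effects gamma
    entering the trait means.  ``family_size`` controls the block-diagonal
    kinship (within-family relationship 0.5); the last family absorbs any
    remainder.  One seed fixes the entire output stream.
    """

    n: int = 500
    m: int = 500
    t: int = 1
    p: int = 3
    family_size: int = 4
    h2: float | tuple = 0.5
    sigma2: float | tuple = 1.0
    causal: dict[int, float] = field(default_factory=dict)
    beta_L: np.ndarray | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.t, self.family_size) < 1 or self.p < 2:
            raise DomainError("all design sizes must be positive (p >= 2)")
        for h in np.atleast_1d(self.h2):
            if not (0.0 <= h < 1.0):
                raise DomainError(f"h2 must lie in [0, 1), got {h}")
        for s in np.atleast_1d(self.sigma2):
            if not s > 0:
                raise DomainError(f"sigma2 must be positive, got {s}")

    def _per_trait(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=np.float64), (self.t,))
        return arr.copy()

    def rng(self, component: int, index: int | None = None) -> np.random.Generator:
        key = (component,) if index is None else (component, index)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key)
        )


def simulate_kinship(config: SimConfig) -> KinshipMatrix:
    """Block-diagonal family kinship: diagonal 1, within-family 0.5.

    Exact, interpretable ground truth (e.g. full sibs); PSD by construction,
    so the eigendecomposition accepts it without clipping.
    """
    n, fs = config.n, config.family_size
    values = np.zeros((n, n))
    start = 0
    while start < n:
        stop = min(start + fs, n)
        values[start:stop, start:stop] = 0.5
        start = stop
    np.fill_diagonal(values, 1.0)
    return KinshipMatrix(values=values, sample_ids=[f"S{i + 1}" for i in range(n)])


def simulate_genotypes(config: SimConfig) -> np.ndarray:
    """Independent biallelic dosages: x_j ~ Binomial(2, f_j), f_j ~ U(maf_range).

    Relatedness enters the model through Phi only; the two-step scan needs
    no linkage disequilibrium.
    """
    rng = config.rng(_GENOTYPES)
    freqs = rng.uniform(*config.maf_range, size=config.m)
    return rng.binomial(2, freqs, size=(config.n, config.m)).astype(np.float64)


def simulate_covariates(config: SimConfig) -> np.ndarray:
    """Covariate matrix X_L: an intercept column plus p-2 standard-normal columns."""
    rng = config.rng(_COVARIATES)
    XL = np.empty((config.n, config.p - 1))
    XL[:, 0] = 1.0
    if config.p > 2:
        XL[:, 1:] = rng.standard_normal((config.n, config.p - 2))
    return XL


def _psd_sqrt(phi: np.ndarray) -> np.ndarray:
    lam, V = scipy.linalg.eigh((phi + phi.T) / 2.0)
    return V * np.sqrt(np.clip(lam, 0.0, None)) @ V.T


def simulate_phenotypes(
    config: SimConfig,
    phi: KinshipMatrix | np.ndarray,
    genotypes: np.ndarray,
    XL: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the n x t phenotype matrix from the generative mixed model.

    Each trait j gets an independent polygenic draw g ~ N(0, sigma²_j h²_j Phi)
    and noise e ~ N(0, sigma²_j (1-h²_j) I) from its own substreams; identical
    seeds yield bit-identical output.
    """
    phi_values = phi.values if isinstance(phi, KinshipMatrix) else np.asarray(phi)
    if phi_values.shape[0] != config.n or genotypes.shape[0] != config.n:
        raise DimensionError("kinship/genotypes disagree with the configured n")
    h2 = config._per_trait(config.h2)
    sigma2 = config._per_trait(config.sigma2)
    if XL is None:
        XL = simulate_covariates(config)
    beta_L = (np.zeros(XL.shape[1]) if config.beta_L is None
              else np.asarray(config.beta_L, dtype=np.float64))
    mean = XL @ beta_L
    for snp_idx, gamma in config.causal.items():
        mean = mean + genotypes[:, snp_idx] * gamma
    root = _psd_sqrt(phi_values)
    Y = np.empty((config.n, config.t))
    for j in range(config.t):
        g = root @ config.rng(_GENETIC, j).standard_normal(config.n)
        e = config.rng(_ENVIRONMENT, j).standard_normal(config.n)
        Y[:, j] = (mean
                   + np.sqrt(sigma2[j] * h2[j]) * g
                   + np.sqrt(sigma2[j] * (1.0 - h2[j])) * e)
    return Y


def simulate_dataset(config: SimConfig):
    """Full cohort: ``(phi, genotypes, XL, Y, truth)`` with ground truth dict."""
    phi = simulate_kinship(config)
    genotypes = simulate_genotypes(config)
    XL = simulate_covariates(config)
    Y = simulate_phenotypes(config, phi, genotypes, XL=XL)
    truth = {
        "h2": config._per_trait(config.h2),
        "sigma2": config._per_trait(config.sigma2),
        "causal": dict(config.causal),
    }
    return phi, genotypes, XL, Y, truth


def ratio_traits(base: np.ndarray, labels: list[str] | None = None):
    """Expand k base measurements into all k² traits: originals + ordered ratios.

    Metabolomics convention: the k originals followed by every ordered pair
    column_i / column_j (i != j), so k base columns yield k² traits (328
    measurements expand to 107,584).  Labels follow the "A", "A/B" pattern.

    Returns ``(expanded, labels)``.
    """
    base = np.atleast_2d(np.asarray(base, dtype=np.float64))
    n, k = base.shape
    bad = np.argwhere(~(base > 0))
    if bad.size:
        i, j = bad[0]
        raise DomainError(
            f"ratio traits need strictly positive values; "
            f"cell (row {i}, column {j}) is {base[i, j]!r}"
        )
    if labels is None:
        labels = [f"M{j + 1}" for j in range(k)]
    if len(labels) != k:
        raise DimensionError(f"{len(labels)} labels for {k} base columns")
    out = np.empty((n, k * k))
    out_labels: list[str] = []
    out[:, :k] = base
    out_labels.extend(labels)
    col = k
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            out[:, col] = base[:, i] / base[:, j]
            out_labels.append(f"{labels[i]}/{labels[j]}")
            col += 1
    return out, out_labels


def mean_impute(y: np.ndarray) -> np.ndarray:
    """Replace missing (NaN) entries by the observed mean; columns of a
    matrix are imputed independently.  Observed entries are untouched."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 2:
        return np.column_stack([mean_impute(y[:, j]) for j in range(y.shape[1])])
    observed = np.isfinite(y)
    if not observed.any():
        raise DomainError("cannot impute an all-missing vector")
    out = y.copy()
    out[~observed] = y[observed].mean()
    return out


def genomic_kinship(genotypes: np.ndarray,
                    sample_ids: list[str] | None = None) -> KinshipMatrix:
    """Genomic relationship matrix Phi = Z Zᵀ / m from standardized dosages.

    Z standardizes each dosage column to zero mean and unit variance;
    monomorphic columns carry no relatedness information and are dropped
    with a warning.  Offered for cohorts without a pedigree-based kinship.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=np.float64))
    n, m = G.shape
    if m < 2:
        raise DomainError("genomic kinship needs at least 2 SNPs")
    sd = G.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise DomainError("all SNP columns are monomorphic")
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic SNP columns from the GRM",
            UserWarning,
            stacklevel=2,
        )
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    values = Z @ Z.T / Z.shape[1]
    values = (values + values.T) / 2.0
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return KinshipMatrix(values=values, sample_ids=sample_ids)
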