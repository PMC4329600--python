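"""Cost model and automatic engine selection.

Both engines share step one (one kinship eigendecomposition plus ~v
likelihood evaluations per trait); they differ in the scan.  Per trait the
Cholesky engine pays an n³/6 factorization plus n²/2 multiply-adds to whiten
each of the m SNP columns — O(t·m·n²) in total.  The eigen-rotation engine
pays the rotations once, O(n²(m + t)), after which every grid cell is an
O(n·p) weighted solve — O(m·t·n) when both m and t exceed n.  Affine in t
against affine in t with a much smaller slope: the predicted costs cross at
a handful of traits and the selector simply picks the smaller total.

The model's per-kernel multiply-add formulas are the very ones the runtime
operation counter charges (see :mod:`lmmscan.instrument`), so predictions
are calibrated to the instrumented implementation by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .instrument import (
    madds_cell_solve,
    madds_cholesky,
    madds_dot,
    madds_eigh,
    madds_gemv,
    madds_syrk,
    madds_trsv,
)
from .model import DomainError

__all__ = [
    "CostEstimate",
    "predict_costs",
    "select_algorithm",
    "memory_budget",
    "DEFAULT_V",
]

#: Default likelihood-evaluation budget per trait in step one (grid sweep
#: plus bounded refinement).
DEFAULT_V = 50


@dataclass
class CostEstimate:
    """Modeled cost of one algorithm on a given design.

    ``flops`` counts multiply-adds: the shared step-one work plus the
    engine-specific scan (both recorded in ``breakdown``).
    ``memory_entries`` is the minimum working set, n² + (2+p)·n entries
    (kinship-sized buffer plus one resident SNP, one trait, and the
    covariates).
    """

    algorithm: str
    flops: float
    memory_entries: float
    breakdown: dict[str, float]


def _shared_setup(n: int, t: int, p: int, v: int) -> float:
    """Step one: one eigendecomposition plus t·v profiled-likelihood evals."""
    q = p - 1
    per_eval = madds_dot(n) * (q + 3) + n * q * q  # weighting + WLS fit + RSS
    return madds_eigh(n) + (t + q) * madds_gemv(n, n) + t * v * per_eval


def _chol_engine(n: int, m: int, t: int, p: int) -> dict[str, float]:
    q = p - 1
    return {
        "cholesky": t * madds_cholesky(n),
        "whiten_covariates": t * ((q + 1) * madds_trsv(n)
                                  + madds_syrk(n, q) + madds_gemv(n, q)),
        "whiten_snps": t * m * madds_trsv(n),
        "scan": t * m * (madds_gemv(n, q) + 2 * madds_dot(n)
                         + madds_cell_solve(q)),
    }


def _eig_engine(n: int, m: int, t: int, p: int, block_cols: int) -> dict[str, float]:
    q = p - 1
    n_blocks = math.ceil(m / block_cols)
    per_trait_block = (
        madds_dot(n) + q * madds_dot(n)                # weights, weighted covariates
        + madds_syrk(n, q) + madds_gemv(n, q)          # covariate cross-products
    )
    per_cell = 3 * madds_dot(n) + madds_gemv(n, q) + madds_cell_solve(q)
    return {
        "rotations": (q + t + m) * madds_gemv(n, n),
        "trait_products": t * n_blocks * per_trait_block,
        "wls": m * t * per_cell,
    }


def predict_costs(
    n: int, m: int, t: int, p: int, v: int = DEFAULT_V, block_cols: int = 256
) -> list[CostEstimate]:
    """Modeled multiply-add totals and working sets for both engines.

    Mirrors the instrumented kernel charges; ``v`` is the per-trait
    likelihood-evaluation budget of step one, shared by both algorithms.
    """
    if min(n, m, t, p, v, block_cols) < 1:
        raise DomainError("design sizes must be positive integers")
    shared = _shared_setup(n, t, p, v)
    mem = float(memory_budget(n, p, 2))
    estimates = []
    for name, components in (("chol", _chol_engine(n, m, t, p)),
                             ("eig", _eig_engine(n, m, t, p, block_cols))):
        engine = float(sum(components.values()))
        estimates.append(CostEstimate(
            algorithm=name,
            flops=shared + engine,
            memory_entries=mem,
            breakdown={"shared": shared, "engine": engine, **components},
        ))
    return estimates


def select_algorithm(n: int, m: int, t: int, p: int, v: int = DEFAULT_V) -> str:
    """Pick the engine with the smaller predicted flop total.

    Single-trait (and very-few-trait) designs land on the Cholesky engine;
    past a handful of traits the eigen-rotation engine wins.  An explicit
    user choice always overrides the selector at the CLI level.
    """
    estimates = predict_costs(n, m, t, p, v)
    return min(estimates, key=lambda e: e.flops).algorithm


def memory_budget(n: int, p: int, k: int) -> int:
    """Working-set contract: n² + (k+p)·n entries.

    ``k`` counts SNP and trait columns resident in memory at once; the
    minimum k = 2 (one SNP, one trait) gives the n² + (2+p)·n floor.  The
    engines' instrumented peak allocations must stay under this bound.
    """
    if k < 2:
        raise DomainError(f"k must be >= 2 (one SNP and one trait), got {k}")
    if n < 1 or p < 1:
        raise DomainError("n and p must be positive")
    return n * n + (k + p) * n
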