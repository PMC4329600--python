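"""Operation counting and working-set accounting.

The scan engines and the cost-model planner share one vocabulary of
per-kernel multiply-add counts: each time an engine executes a linear-algebra
kernel it charges the textbook multiply-add count of that call to a named
phase, and the planner sums the same formulas analytically.  Counted totals
therefore measure the work the implementation actually dispatched, while
staying deterministic and independent of BLAS internals.

`MemoryMeter` tracks the engines' named large allocations (in matrix
*entries*, not bytes) so the blocked-streaming working-set bound
n² + (k+p)·n can be asserted rather than assumed.
"""

from __future__ import annotations

from collections import defaultdict


# ---------------------------------------------------------------------------
# Per-kernel multiply-add counts (double-precision real arithmetic)
# ---------------------------------------------------------------------------

def madds_cholesky(n: int) -> float:
    """Cholesky factorization of an n x n SPD matrix."""
    return n ** 3 / 6.0


def madds_eigh(n: int) -> float:
    """Full symmetric eigendecomposition (values + vectors), LAPACK-style.

    The conventional estimate for tridiagonalization plus back-transformation
    of all eigenvectors; treated as the kernel's charge, not a wall-clock model.
    """
    return 9.0 * n ** 3


def madds_trsv(n: int) -> float:
    """Triangular solve with a single right-hand side of length n."""
    return n * (n + 1) / 2.0


def madds_gemv(n: int, k: int) -> float:
    """Dense matrix-vector product with an n x k matrix."""
    return float(n) * k


def madds_dot(n: int) -> float:
    return float(n)


def madds_syrk(n: int, k: int) -> float:
    """Symmetric rank-k cross-product AᵀA for an n x k matrix."""
    return n * k * (k + 1) / 2.0


def madds_cell_solve(q: int) -> float:
    """Partitioned p x p normal-equation solve given a cached q x q factor.

    Two cached triangular solves of size q, the Schur pivot, and the
    covariance assembly; q = p - 1 covariate coefficients.
    """
    return q * (q + 1.0) + q * q + 3.0 * q + 5.0


class OpCounter:
    """Accumulates multiply-add charges per phase plus kernel call counts."""

    def __init__(self) -> None:
        self.madds: dict[str, float] = defaultdict(float)
        self.calls: dict[str, int] = defaultdict(int)

    def add(self, phase: str, count: float) -> None:
        self.madds[phase] += count

    def call(self, event: str, k: int = 1) -> None:
        self.calls[event] += k

    def total(self) -> float:
        return float(sum(self.madds.values()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{k}={v:.3g}" for k, v in sorted(self.madds.items()))
        return f"OpCounter({parts})"


class MemoryMeter:
    """Peak working-set tracker in units of 8-byte matrix entries.

    Engines register every O(n²) or O(n·block) allocation by name and release
    it when the buffer is dropped; `peak_entries` is compared against the
    planner's memory budget in tests.
    """

    def __init__(self) -> None:
        self._live: dict[str, float] = {}
        self.current = 0.0
        self.peak_entries = 0.0

    def alloc(self, name: str, entries: float) -> None:
        if name in self._live:
            self.free(name)
        self._live[name] = float(entries)
        self.current += float(entries)
        if self.current > self.peak_entries:
            self.peak_entries = self.current

    def free(self, name: str) -> None:
        entries = self._live.pop(name, 0.0)
        self.current -= entries
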