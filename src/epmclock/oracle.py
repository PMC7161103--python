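"""Naive design-matrix least squares for the molecular-clock fit.

This is the reference ("slow") route: it materializes the full nm x 2n design
matrix X — row (i*m + j) has t_j at column i and 1 at column n + i — and
solves the least-squares problem for beta = (r_1..r_n, s^0_1..s^0_n).  It
exists to validate the closed-form site step and is deliberately gated to
small instances; the fast path never builds X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AgeVector, MethylationMatrix, SiteParameters
from .exceptions import DegenerateAgesError

__all__ = ["DesignSystem", "build_design_system", "solve_mc_naive"]

# cap on materialized X entries (nm rows x 2n cols) for the naive engine
_MAX_DESIGN_ENTRIES = 50_000_000


@dataclass
class DesignSystem:
    """Explicit least-squares system: X (nm x 2n) and flattened observations y."""

    X: np.ndarray
    y: np.ndarray
    n: int
    m: int


def build_design_system(matrix: MethylationMatrix, ages: AgeVector) -> DesignSystem:
    """Materialize the design matrix in site-major, individual-minor row order."""
    n, m = matrix.values.shape
    if ages.m != m:
        raise ValueError(f"ages length {ages.m} != matrix individuals {m}")
    if n * m * 2 * n > _MAX_DESIGN_ENTRIES:
        raise ValueError(
            "instance too large for the naive engine "
            f"(design matrix would hold {n * m * 2 * n} entries)"
        )
    t = ages.ages
    X = np.zeros((n * m, 2 * n))
    for i in range(n):
        rows = slice(i * m, (i + 1) * m)
        X[rows, i] = t
        X[rows, n + i] = 1.0
    y = matrix.values.reshape(-1)  # row-major: entry i*m + j is s_hat[i, j]
    return DesignSystem(X=X, y=y, n=n, m=m)


def solve_mc_naive(system: DesignSystem) -> SiteParameters:
    """Least-squares solve of the explicit system; the slow correctness oracle.

    Uses a numerically stable solver rather than literally inverting X^T X;
    the contract is the RSS minimizer, which is identical when ages are not
    all equal.
    """
    t = system.X[: system.m, 0]
    if np.all(t == t[0]):
        raise DegenerateAgesError("degenerate ages: normal matrix is singular")
    beta, *_ = np.linalg.lstsq(system.X, system.y, rcond=None)
    n = system.n
    return SiteParameters(rates=beta[:n], start_states=beta[n:])
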