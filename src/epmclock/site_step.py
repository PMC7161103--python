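"""Closed-form site step: per-site rate and start state in O(nm).

Because each row of the design matrix touches only one site's two unknowns,
the 2n x 2n normal matrix X^T X is four diagonal blocks built from three
scalars (sum of ages, sum of squared ages, and m), and its inverse factors
through a single scalar

    lam = 1 / ((sum t)^2 - m * sum t^2),

which is strictly negative whenever at least two ages differ.  The projector
(X^T X)^{-1} X^T then has one m-wide band per output coordinate, with band
coefficients depending only on the individual index j:

    u_j = -m * t_j + sum t        (rate row),
    l_j = t_j * sum t - sum t^2   (start-state row),

so a full least-squares solve collapses to two banded dot products per site:
r_i = lam * sum_j u_j * s_hat[i, j] and s0_i = lam * sum_j l_j * s_hat[i, j].
No matrix is ever constructed, multiplied, or inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AgeVector, MethylationMatrix, SiteParameters
from .counting import MultiplicationCounter
from .exceptions import DegenerateAgesError

__all__ = [
    "TimeMoments",
    "compute_time_moments",
    "projection_band",
    "assemble_normal_matrix",
    "NormalMatrixBlocks",
    "site_step",
]


def _ages_array(ages: AgeVector | np.ndarray) -> np.ndarray:
    if isinstance(ages, AgeVector):
        return ages.ages
    return np.asarray(ages, dtype=float).ravel()


@dataclass(frozen=True)
class TimeMoments:
    """The whole state the site step needs beyond the data matrix.

    sum_t, sum_t2 are the first two power sums of the m ages; lam is the
    scalar common factor of the structured inverse.  lam < 0 strictly, by
    Cauchy-Schwarz, with equality excluded because all-equal ages are
    rejected.
    """

    sum_t: float
    sum_t2: float
    m: int
    lam: float


def compute_time_moments(ages: AgeVector | np.ndarray) -> TimeMoments:
    """Age sums and the inverse scalar lam, computed once per site step."""
    t = _ages_array(ages)
    m = t.size
    if m < 2 or np.all(t == t[0]):
        raise DegenerateAgesError("degenerate ages: Λ undefined")
    sum_t = float(t.sum())
    sum_t2 = float(t @ t)
    denom = sum_t * sum_t - m * sum_t2
    if denom == 0.0:
        raise DegenerateAgesError("degenerate ages: Λ undefined")
    return TimeMoments(sum_t=sum_t, sum_t2=sum_t2, m=m, lam=1.0 / denom)


def projection_band(
    moments: TimeMoments,
    ages: AgeVector | np.ndarray,
    counter: MultiplicationCounter | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Band coefficients (u, l) of the structured projector, pre-lam.

    The band is identical for every site row (it depends only on j), so it is
    computed once as two length-m vectors and reused for all n sites.
    """
    t = _ages_array(ages)
    u = -moments.m * t + moments.sum_t
    l = t * moments.sum_t - moments.sum_t2
    if counter is not None:
        counter.add(2 * moments.m)  # one multiplication per u_j and per l_j
    return u, l


@dataclass(frozen=True)
class NormalMatrixBlocks:
    """X^T X described by its four diagonal scalars; never materialized on the fast path."""

    a: float  # upper-left diagonal value, sum of squared ages
    b: float  # upper-right == lower-left diagonal value, sum of ages
    d: float  # lower-right diagonal value, m
    lam: float

    def dense(self, n: int) -> np.ndarray:
        """Dense 2n x 2n expansion of X^T X, for inspection and testing only."""
        eye = np.eye(n)
        return np.block([[self.a * eye, self.b * eye], [self.b * eye, self.d * eye]])

    def inverse_dense(self, n: int) -> np.ndarray:
        """Dense expansion of (X^T X)^{-1} = lam * [[-m, sum t], [sum t, -sum t^2]]."""
        eye = np.eye(n)
        return self.lam * np.block(
            [[-self.d * eye, self.b * eye], [self.b * eye, -self.a * eye]]
        )


def assemble_normal_matrix(moments: TimeMoments, n: int) -> NormalMatrixBlocks:
    """Structured description of X^T X from the time moments alone."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return NormalMatrixBlocks(
        a=moments.sum_t2, b=moments.sum_t, d=float(moments.m), lam=moments.lam
    )


def site_step(
    matrix: MethylationMatrix | np.ndarray,
    ages: AgeVector | np.ndarray,
    counter: MultiplicationCounter | None = None,
) -> SiteParameters:
    """Exact RSS minimizer over all (r_i, s0_i) for fixed ages, in O(nm).

    For each site i:  r_i = lam * sum_j u_j * s_hat[i, j]  and
    s0_i = lam * sum_j l_j * s_hat[i, j].  Accumulation runs in ascending j
    (the contiguous row layout) so results are bit-reproducible; lam is a
    single scalar applied after accumulation.

    ``counter``, if given, tallies the 2m band-construction and 2nm
    band-application multiplications — the linear operation count the
    structured solution achieves.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else np.asarray(matrix, dtype=float)
    t = _ages_array(ages)
    if values.shape[1] != t.size:
        raise ValueError(f"matrix has {values.shape[1]} individuals but {t.size} ages")
    moments = compute_time_moments(t)
    u, l = projection_band(moments, t, counter=counter)
    ru = values @ u
    sl = values @ l
    if counter is not None:
        counter.add(2 * values.shape[0] * moments.m)
    return SiteParameters(rates=moments.lam * ru, start_states=moments.lam * sl)
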