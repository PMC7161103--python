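"""Closed-form time step: per-individual epigenetic-age update.

With site parameters frozen, the residual sum of squares is quadratic in
each t_j separately, so the unique coordinate minimizer is the rational form

    t_j = sum_i r_i * (s_hat[i, j] - s0_i) / sum_i r_i^2,

a rate-weighted regression of each individual's methylation displacement
onto the site rates.  The denominator is computed once (n multiplications);
the numerators cost nm, giving the O(nm) bound.
"""

from __future__ import annotations

import numpy as np

from .containers import EpigeneticAges, MethylationMatrix, SiteParameters
from .counting import MultiplicationCounter
from .exceptions import ZeroRatesError

__all__ = ["time_step"]

# below this, sum r_i^2 has effectively underflowed and times are unidentifiable
_RATE_NORM_FLOOR = 1e-300


def time_step(
    matrix: MethylationMatrix | np.ndarray,
    params: SiteParameters,
    counter: MultiplicationCounter | None = None,
) -> EpigeneticAges:
    """Exact RSS minimizer over all t_j for fixed site parameters.

    Returned ages are unconstrained: values below zero or beyond the
    chronological range express age deceleration/acceleration and are
    reported as-is.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else np.asarray(matrix, dtype=float)
    r = params.rates
    if values.shape[0] != r.size:
        raise ValueError(f"matrix has {values.shape[0]} sites but {r.size} rates")
    rr = float(r @ r)
    if counter is not None:
        counter.add(r.size)
    if rr < _RATE_NORM_FLOOR:
        raise ZeroRatesError("times unidentifiable: all rates zero")
    numer = r @ (values - params.start_states[:, None])
    if counter is not None:
        counter.add(values.size)  # one product r_i * (s_hat - s0) per matrix entry
    return EpigeneticAges(e_ages=numer / rr)
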