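"""Likelihood-ratio comparison of the nested molecular-clock and pacemaker fits.

The MC model (times fixed at chronological ages) is nested in the EPM model
(times free), so with Gaussian residuals the deviance is

    chi2 = -2 log(L0 / L1) = n * m * log(RSS_MC / RSS_EPM),

natural log throughout, referred to a chi-square with df equal to the number
of time parameters freed under EPM — one per individual, df = m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import AgeVector, MethylationMatrix
from .cem import CEMConfig, FitResult, fit_epm, fit_mc
from .exceptions import NestingViolationError

__all__ = ["LRTResult", "likelihood_ratio_test", "compare_models"]

# relative RSS_EPM > RSS_MC excess tolerated as round-off and clamped to ratio 1
_NESTING_RTOL = 1e-9
# below this, an RSS is pure floating round-off of an exact fit; two such fits
# are indistinguishable and their ratio carries no information
_PERFECT_FIT_FLOOR = 1e-20


@dataclass(frozen=True)
class LRTResult:
    """Chi-square statistic, degrees of freedom, and upper-tail p-value."""

    chi2: float
    df: int
    p_value: float
    rss_mc: float
    rss_epm: float


def likelihood_ratio_test(
    rss_mc: float,
    rss_epm: float,
    n: int,
    m: int,
    df: int | None = None,
) -> LRTResult:
    """LRT of the MC null against the EPM alternative from their fitted RSS.

    Parameters
    ----------
    rss_mc, rss_epm
        Minimized residual sums of squares of the two fits; must satisfy
        rss_epm <= rss_mc up to round-off (the models are nested).
    n, m
        Number of sites and individuals (nm observations total).
    df
        Degrees of freedom; defaults to m, the count of freed time
        parameters.  Overridable for sensitivity analyses.
    """
    if rss_mc < 0 or rss_epm < 0:
        raise ValueError("RSS inputs must be nonnegative")
    if df is not None and df < 1:
        raise ValueError("df must be >= 1")
    if max(rss_mc, rss_epm) <= _PERFECT_FIT_FLOOR:
        # both models fit to round-off; no evidence either way
        return LRTResult(chi2=0.0, df=df if df is not None else m, p_value=1.0,
                         rss_mc=rss_mc, rss_epm=rss_epm)
    if rss_mc <= 0:
        raise ValueError("RSS_MC must be positive (log undefined otherwise)")
    if rss_epm > rss_mc:
        excess = (rss_epm - rss_mc) / rss_mc
        if excess > _NESTING_RTOL:
            raise NestingViolationError(
                f"RSS_EPM exceeds RSS_MC by relative {excess:.3g}; models are nested"
            )
        rss_epm = rss_mc
    if df is None:
        df = m
    if rss_epm == 0.0:
        warnings.warn(
            "perfect EPM fit (RSS_EPM = 0): chi2 reported as +inf, p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return LRTResult(chi2=np.inf, df=df, p_value=0.0,
                         rss_mc=rss_mc, rss_epm=rss_epm)
    chi2 = n * m * float(np.log(rss_mc / rss_epm))
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p_value=p, rss_mc=rss_mc, rss_epm=rss_epm)


def compare_models(
    matrix: MethylationMatrix,
    ages: AgeVector,
    config: CEMConfig | None = None,
    engine: str = "closed_form",
) -> tuple[LRTResult, FitResult, FitResult]:
    """Run both fits on the same data and test MC against EPM."""
    mc = fit_mc(matrix, ages, engine=engine)
    epm = fit_epm(matrix, ages, config=config, engine=engine)
    lrt = likelihood_ratio_test(
        mc.final_rss, epm.final_rss, matrix.n_sites, matrix.n_individuals
    )
    return lrt, mc, epm
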