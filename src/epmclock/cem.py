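"""RSS objective and the alternating conditional-EM driver.

The fitter minimizes

    RSS = sum_i sum_j (s_hat[i, j] - (s0_i + r_i * t_j))^2,

equivalent to maximizing the Gaussian likelihood.  The molecular-clock (MC)
fit holds t at the chronological ages and takes one closed-form site step.
The pacemaker (EPM) fit alternates exact conditional minimizations — site
step over (r, s0), then time step over t — each of which cannot increase the
RSS, so the trace is non-increasing and the procedure reaches a local
optimum.  Times are initialized to the chronological ages, which also pins
down the affine gauge freedom of the model: for any a != 0 and b, the map
(t, r, s0) -> (a*t + b, r/a, s0 - (b/a)*r) leaves the RSS unchanged, so
absolute e-age values are only meaningful relative to that anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AgeVector, EpigeneticAges, MethylationMatrix, SiteParameters
from .exceptions import EPMError, ZeroRatesError
from .site_step import site_step
from .time_step import time_step

logger = logging.getLogger(__name__)

__all__ = ["CEMConfig", "FitResult", "rss", "fit_mc", "fit_epm"]


@dataclass(frozen=True)
class CEMConfig:
    """Stopping rule for the alternating fit.

    delta_cem
        Threshold on the RSS improvement of one full iteration (site step +
        time step); iteration stops once the improvement is <= delta_cem.
    improvement_mode
        ``"absolute"`` compares the raw RSS decrease; ``"relative"`` divides
        the decrease by the RSS at the start of the iteration, which is
        robust to the overall scale of the data.
    """

    delta_cem: float = 1e-6
    max_iters: int = 100
    improvement_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.delta_cem <= 0:
            raise ValueError("delta_cem must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.improvement_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown improvement_mode {self.improvement_mode!r}")


@dataclass
class FitResult:
    """Converged parameters, epigenetic ages, and the RSS trajectory."""

    params: SiteParameters
    e_ages: EpigeneticAges
    rss_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    model: str = "epm"

    @property
    def final_rss(self) -> float:
        return self.rss_trace[-1]


def rss(
    matrix: MethylationMatrix | np.ndarray,
    params: SiteParameters,
    ages: np.ndarray | AgeVector | EpigeneticAges,
) -> float:
    """Residual sum of squares of the linear site trajectories at the given times."""
    values = matrix.values if isinstance(matrix, MethylationMatrix) else np.asarray(matrix, dtype=float)
    if isinstance(ages, AgeVector):
        t = ages.ages
    elif isinstance(ages, EpigeneticAges):
        t = ages.e_ages
    else:
        t = np.asarray(ages, dtype=float).ravel()
    resid = values - (params.start_states[:, None] + np.outer(params.rates, t))
    return float(np.einsum("ij,ij->", resid, resid))


def fit_mc(
    matrix: MethylationMatrix, ages: AgeVector, engine: str = "closed_form"
) -> FitResult:
    """Molecular-clock fit: one exact site step at the chronological ages."""
    params = _site_step_engine(matrix, ages, engine)
    final = rss(matrix, params, ages.ages)
    return FitResult(
        params=params,
        e_ages=EpigeneticAges(e_ages=ages.ages.copy()),
        rss_trace=[final],
        iterations=1,
        converged=True,
        model="mc",
    )


def fit_epm(
    matrix: MethylationMatrix,
    ages: AgeVector,
    config: CEMConfig | None = None,
    engine: str = "closed_form",
) -> FitResult:
    """Pacemaker fit by alternating exact conditional minimizations.

    Starts from the chronological ages, runs {site step; time step} per
    iteration recording the RSS after each half-step, and stops when the
    per-iteration improvement drops to config.delta_cem or max_iters is hit.
    """
    cfg = config or CEMConfig()
    t = ages.ages.astype(float).copy()
    trace: list[float] = []
    params: SiteParameters | None = None
    converged = False
    iterations = 0
    prev = np.inf
    for it in range(1, cfg.max_iters + 1):
        params = _site_step_engine(matrix, t, engine)
        trace.append(rss(matrix, params, t))
        try:
            t = time_step(matrix, params).e_ages
        except ZeroRatesError as exc:
            raise EPMError(f"iteration {it}: {exc}") from exc
        current = rss(matrix, params, t)
        trace.append(current)
        iterations = it
        logger.debug("iteration %d: rss=%.6g", it, current)
        improvement = prev - current
        if cfg.improvement_mode == "relative" and np.isfinite(prev) and prev > 0:
            improvement /= prev
        if improvement <= cfg.delta_cem:
            converged = True
            break
        prev = current
    assert params is not None
    return FitResult(
        params=params,
        e_ages=EpigeneticAges(e_ages=t),
        rss_trace=trace,
        iterations=iterations,
        converged=converged,
        model="epm",
    )


def _site_step_engine(
    matrix: MethylationMatrix, ages: AgeVector | np.ndarray, engine: str
) -> SiteParameters:
    if engine == "closed_form":
        return site_step(matrix, ages)
    if engine == "naive":
        from .oracle import build_design_system, solve_mc_naive

        if isinstance(ages, np.ndarray):
            ages = AgeVector(
                ages=ages, individual_ids=list(matrix.individual_ids)
            )
        return solve_mc_naive(build_design_system(matrix, ages))
    raise ValueError(f"unknown engine {engine!r}")
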