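"""Seeded generators for methylation matrices under the MC and EPM models.

Both generators draw from a single ``numpy.random.Generator`` in a fixed,
documented order — ages, rates, start states, (EPM only: dilation
multipliers), noise — so a seed fully determines the output and an EPM run
whose dilation distribution is degenerate at 1 reproduces the MC run for the
same seed exactly.

Default distributions (all overridable):

* chronological ages uniform on [0, 100] years;
* rates: random sign times a magnitude uniform on [0.001, 0.01] per year —
  the dead zone below 0.001 keeps every site informative about time;
* start states uniform on [0.1, 0.9];
* dilation multipliers log-normal with median 1 (sigma_log = 0.2);
* noise s.d. sigma = 0.02, roughly a tenth of a typical site's dynamic
  range over the age span.

Generated levels are NOT clipped to [0, 1] by default: the estimator assumes
a linear-Gaussian model and clipping breaks it.  An optional clip flag
exists for realism demonstrations only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import AgeVector, MethylationMatrix

__all__ = ["SimulationTruth", "simulate_mc", "simulate_epm", "sigma_for_snr"]

Dist = Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind a simulated matrix."""

    rates: np.ndarray
    start_states: np.ndarray
    sigma: float
    chrono_ages: np.ndarray
    epigenetic_ages: np.ndarray
    seed: int


def sigma_for_snr(truth: "SimulationTruth", snr: float) -> float:
    """Noise s.d. giving an average per-site signal-to-noise ratio of ``snr``.

    A site's signal is the spread of its age-driven component, |r_i| times
    the standard deviation of the true (epigenetic) ages; averaging over
    sites and dividing by the target ratio yields sigma.  Typical use: run a
    generator once with sigma=0 to obtain the truth, derive sigma, re-run
    with the same seed (noise is drawn last, so all other draws repeat).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signal = float(np.mean(np.abs(truth.rates)) * np.std(truth.epigenetic_ages))
    return signal / snr


def _default_rates(rng: np.random.Generator, n: int) -> np.ndarray:
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * rng.uniform(0.001, 0.01, size=n)


def _default_starts(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.1, 0.9, size=n)


def _default_dilation(rng: np.random.Generator, m: int) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=0.2, size=m)


def _draw_common(
    n: int,
    m: int,
    age_range: tuple[float, float],
    rate_dist: Dist | None,
    start_dist: Dist | None,
    rng: np.random.Generator,
    ages: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n < 1 or m < 2:
        raise ValueError(f"need n >= 1 sites and m >= 2 individuals, got {n}x{m}")
    lo, hi = age_range
    if not hi > lo:
        raise ValueError(f"degenerate age range {age_range}")
    t = rng.uniform(lo, hi, size=m) if ages is None else np.asarray(ages, float)
    if t.size != m:
        raise ValueError(f"{t.size} explicit ages for m={m}")
    r = (rate_dist or _default_rates)(rng, n)
    s0 = (start_dist or _default_starts)(rng, n)
    if r.size != n or s0.size != n:
        raise ValueError("rate/start distributions returned wrong sizes")
    return t, r, s0


def _assemble(
    n: int,
    m: int,
    t_true: np.ndarray,
    r: np.ndarray,
    s0: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    clip: bool,
) -> np.ndarray:
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    values = s0[:, None] + np.outer(r, t_true)
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=(n, m))
    if clip:
        values = np.clip(values, 0.0, 1.0)
    return values


def _package(
    values: np.ndarray, t_chrono: np.ndarray
) -> tuple[MethylationMatrix, AgeVector]:
    n, m = values.shape
    site_ids = [f"site_{i}" for i in range(n)]
    ind_ids = [f"ind_{j}" for j in range(m)]
    return (
        MethylationMatrix(values=values, site_ids=site_ids, individual_ids=ind_ids),
        AgeVector(ages=t_chrono, individual_ids=ind_ids),
    )


def simulate_mc(
    n: int,
    m: int,
    age_range: tuple[float, float] = (0.0, 100.0),
    rate_dist: Dist | None = None,
    start_dist: Dist | None = None,
    sigma: float = 0.02,
    seed: int = 0,
    ages: np.ndarray | None = None,
    clip: bool = False,
) -> tuple[MethylationMatrix, AgeVector, SimulationTruth]:
    """Constant-rate (molecular clock) data: s_hat = s0 + r * t + noise."""
    rng = np.random.default_rng(seed)
    t, r, s0 = _draw_common(n, m, age_range, rate_dist, start_dist, rng, ages)
    values = _assemble(n, m, t, r, s0, sigma, rng, clip)
    matrix, age_vec = _package(values, t)
    truth = SimulationTruth(
        rates=r, start_states=s0, sigma=sigma,
        chrono_ages=t, epigenetic_ages=t.copy(), seed=seed,
    )
    return matrix, age_vec, truth


def simulate_epm(
    n: int,
    m: int,
    age_range: tuple[float, float] = (0.0, 100.0),
    rate_dist: Dist | None = None,
    start_dist: Dist | None = None,
    dilation_dist: Dist | None = None,
    sigma: float = 0.02,
    seed: int = 0,
    ages: np.ndarray | None = None,
    clip: bool = False,
) -> tuple[MethylationMatrix, AgeVector, SimulationTruth]:
    """Pacemaker data: each individual's sites run on a common dilated clock.

    A positive multiplier c_j per individual rescales all of that
    individual's site rates in concert, equivalent to replacing the
    chronological age t_j by a true epigenetic age t*_j = c_j * t_j.  The
    returned AgeVector carries the chronological ages (what a fitter
    observes); the truth object carries t*.
    """
    rng = np.random.default_rng(seed)
    t, r, s0 = _draw_common(n, m, age_range, rate_dist, start_dist, rng, ages)
    c = (dilation_dist or _default_dilation)(rng, m)
    if c.size != m:
        raise ValueError("dilation distribution returned wrong size")
    if np.any(c <= 0):
        raise ValueError("dilation multipliers must be strictly positive")
    t_star = c * t
    values = _assemble(n, m, t_star, r, s0, sigma, rng, clip)
    matrix, age_vec = _package(values, t)
    truth = SimulationTruth(
        rates=r, start_states=s0, sigma=sigma,
        chrono_ages=t, epigenetic_ages=t_star, seed=seed,
    )
    return matrix, age_vec, truth
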