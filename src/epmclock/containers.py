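"""Core in-memory containers for methylation modelling.

Canonical orientation throughout the package is sites x individuals: the
matrix entry ``values[i, j]`` is the observed methylation level of site *i*
in individual *j*, sites are indexed by *i* (n of them) and individuals by
*j* (m of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, DegenerateAgesError

__all__ = [
    "MethylationMatrix",
    "AgeVector",
    "SiteParameters",
    "SiteSelection",
    "EpigeneticAges",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class MethylationMatrix:
    """Observed methylation levels for n sites across m individuals.

    Parameters
    ----------
    values
        Real matrix of shape (n, m); entry (i, j) is the observed level of
        site i in individual j.  Values are typically beta values in [0, 1]
        but the linear-Gaussian model does not constrain them.
    site_ids
        n unique row identifiers.
    individual_ids
        m unique column identifiers.
    """

    values: np.ndarray
    site_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("methylation values must form a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise DataError(f"need at least 1 site and 2 individuals, got {n}x{m}")
        self.site_ids = [str(s) for s in self.site_ids]
        self.individual_ids = [str(s) for s in self.individual_ids]
        if len(self.site_ids) != n:
            raise DataError(f"{len(self.site_ids)} site ids for {n} rows")
        if len(self.individual_ids) != m:
            raise DataError(f"{len(self.individual_ids)} individual ids for {m} columns")
        _check_unique(self.site_ids, "site")
        _check_unique(self.individual_ids, "individual")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                "missing or non-finite methylation value at "
                f"(site {self.site_ids[i]!r}, individual {self.individual_ids[j]!r})"
            )

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def subset_sites(self, indices) -> "MethylationMatrix":
        """Return a new matrix keeping only the given site rows, in order."""
        idx = np.asarray(indices, dtype=int)
        return MethylationMatrix(
            values=self.values[idx, :].copy(),
            site_ids=[self.site_ids[i] for i in idx],
            individual_ids=list(self.individual_ids),
        )


@dataclass
class AgeVector:
    """Chronological ages t_j for the m individuals, in consistent time units.

    Ages may be zero or negative (e.g. gestational time); the only structural
    requirement is that they are not all identical, which would make the
    per-site regressions unsolvable.
    """

    ages: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float).ravel()
        self.individual_ids = [str(s) for s in self.individual_ids]
        if len(self.individual_ids) != self.ages.size:
            raise DataError(
                f"{len(self.individual_ids)} ids for {self.ages.size} ages"
            )
        _check_unique(self.individual_ids, "individual")
        if not np.all(np.isfinite(self.ages)):
            raise DataError("ages must be finite")
        if self.ages.size < 2 or np.all(self.ages == self.ages[0]):
            raise DegenerateAgesError(
                "degenerate ages: all individuals share one age"
            )

    @property
    def m(self) -> int:
        return self.ages.size


@dataclass
class SiteParameters:
    """Per-site methylation rate r_i and start state s_i^0 (level at t = 0)."""

    rates: np.ndarray
    start_states: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float).ravel()
        self.start_states = np.asarray(self.start_states, dtype=float).ravel()
        if self.rates.size != self.start_states.size:
            raise DataError("rates and start states must have equal length")
        if not (np.all(np.isfinite(self.rates)) and np.all(np.isfinite(self.start_states))):
            raise DataError("site parameters must be finite")

    @property
    def n(self) -> int:
        return self.rates.size


@dataclass
class SiteSelection:
    """Result of filtering sites by Pearson correlation with age.

    ``kept_site_indices`` are row indices into the source matrix, sorted by
    descending |correlation|; ``correlations`` carries the signed Pearson r
    of each kept site in the same order.
    """

    kept_site_indices: list[int]
    correlations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float).ravel()
        if len(self.kept_site_indices) != self.correlations.size:
            raise DataError("selection indices and correlations disagree in length")
        if len(set(self.kept_site_indices)) != len(self.kept_site_indices):
            raise DataError("selection indices must be unique")
        if np.any(np.abs(self.correlations) > 1 + 1e-12):
            raise DataError("Pearson correlations must lie in [-1, 1]")


@dataclass
class EpigeneticAges:
    """Estimated epigenetic ages t_j, same units as the input chronological ages.

    No positivity or upper bound is imposed: deviations from chronological age
    are interpreted as age acceleration (e-age > c-age direction chosen by the
    fitted time scale) or deceleration.
    """

    e_ages: np.ndarray

    def __post_init__(self) -> None:
        self.e_ages = np.asarray(self.e_ages, dtype=float).ravel()
        if not np.all(np.isfinite(self.e_ages)):
            raise DataError("epigenetic ages must be finite")

    @property
    def m(self) -> int:
        return self.e_ages.size
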