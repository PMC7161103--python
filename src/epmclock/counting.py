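"""Instrumented accounting of scalar multiplications.

The closed-form site and time steps carry optional counters so the linear
operation-count bounds (2nm + 2m for the site step, nm + n for the time step)
can be verified as literal counts rather than wall-clock measurements.  The
convention is documented in docs/methods.md: the counter tallies band-
coefficient construction and band application for the site step, and per-term
products plus the sum-of-squared-rates preprocessing for the time step.
"""

from __future__ import annotations


class MultiplicationCounter:
    """Accumulates the number of scalar multiplications performed."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count: int = 0

    def add(self, k: int) -> None:
        self.count += int(k)

    def reset(self) -> None:
        self.count = 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultiplicationCounter(count={self.count})"
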