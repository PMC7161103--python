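"""Evaluation helpers for fitted epigenetic ages.

The model has an affine gauge freedom — (t, r, s0) -> (a*t + b, r/a,
s0 - (b/a)*r) leaves the fitted levels unchanged — so estimated and true
e-ages can only be compared after an optimal affine alignment.
"""

from __future__ import annotations

import numpy as np

__all__ = ["affine_align", "aligned_pearson"]


def affine_align(estimate: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Least-squares map a*estimate + b onto truth; returns the aligned estimate."""
    est = np.asarray(estimate, float).ravel()
    tru = np.asarray(truth, float).ravel()
    if est.size != tru.size:
        raise ValueError("length mismatch")
    A = np.column_stack([est, np.ones_like(est)])
    (a, b), *_ = np.linalg.lstsq(A, tru, rcond=None)
    return a * est + b


def aligned_pearson(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between truth and the affine-aligned estimate."""
    aligned = affine_align(estimate, truth)
    tru = np.asarray(truth, float).ravel()
    return float(np.corrcoef(aligned, tru)[0, 1])
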