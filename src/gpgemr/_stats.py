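"""Small numerical helpers shared across modules.

p-value <-> z-score conversions are done in log space throughout: TWAS hits
on strong loci can reach p ~ 1e-160, far below float64 underflow territory
once squared, so every two-sided p is carried as log10(p) wherever it might
be extreme.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_LN10 = np.log(10.0)


def log10_pvalue_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal log10 p-value for a z-score, safe for |z| ~ 30+."""
    z = np.abs(z)
    # log p = log 2 + log Phi(-|z|)
    return (np.log(2.0) + special.log_ndtr(-z)) / _LN10


def pvalue_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value (underflows to 0 for huge z; see log10 form)."""
    return np.exp(np.log(2.0) + special.log_ndtr(-np.abs(z)))


def z_from_pvalue(p: float | np.ndarray) -> float | np.ndarray:
    """|z| matching a two-sided p, via the normal quantile in log space."""
    return -special.ndtri_exp(np.log(np.asarray(p, dtype=float)) - np.log(2.0))


def clip_psd(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue truncation.

    Returns the input untouched when its smallest eigenvalue is already
    above ``-tol`` (the common case for empirical correlation matrices).
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    eigvals = np.linalg.eigvalsh(m)
    if eigvals[0] >= -tol:
        return m
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T
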