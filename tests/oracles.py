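"""Independent oracles used by the test suite.

Everything here is deliberately written as plain loops / closed forms so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def constant_q_e0(q: float, n_ages: int, ax: float = 0.5, closure_mx: float | None = None):
    """Remaining LE at the first age for a constant death probability.

    Brute-force geometric summation: l_k = (1-q)^k, d_k = l_k q,
    L_k = l_{k+1} + ax d_k, summed term by term over the n_ages interior ages;
    the open interval then contributes l_n / closure_mx person-years.
    """
    total = 0.0
    for k in range(n_ages):
        lk = (1.0 - q) ** k
        dk = lk * q
        lk1 = lk - dk
        total += lk1 + ax * dk
    ln = (1.0 - q) ** n_ages
    if closure_mx:
        total += ln / closure_mx
    else:
        total += ax * ln
    return total


def step_hazard_le(mx: np.ndarray, start_index: int = 0) -> float:
    """Remaining LE under a piecewise-constant hazard (one value per year).

    Closed form per interval: a cohort entering with survival S spends
    S (1 - e^-m) / m person-years in it; beyond the last supplied age the
    hazard is held constant (exponential tail S / m).
    """
    le = 0.0
    S = 1.0
    for m in np.asarray(mx, dtype=float)[start_index:]:
        le += S * (1.0 - np.exp(-m)) / m
        S *= np.exp(-m)
    le += S / float(mx[-1])
    return le


def local_cubic_graduation(y: np.ndarray, order: int) -> np.ndarray:
    """Window-by-window least-squares cubic, evaluated at the window centre.

    Endpoints keep the boundary-window polynomial evaluated at their offset.
    """
    y = np.asarray(y, dtype=float)
    half = order // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - order)
        window = y[lo : lo + order]
        coeffs = np.polyfit(np.arange(order), window, 3)
        out[i] = np.polyval(coeffs, i - lo)
    return out
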