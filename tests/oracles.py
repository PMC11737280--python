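"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: plain
Python loops over the direct-sum definitions.
"""

from __future__ import annotations

import math


def xcorr_oracle(x, y, max_lag):
    """Direct-sum normalized cross-correlation over lags -max_lag..+max_lag."""
    n = len(x)
    sx = sum(v * v for v in x)
    sy = sum(v * v for v in y)
    denom = math.sqrt(sx * sy)
    out = []
    for tau in range(-max_lag, max_lag + 1):
        total = 0.0
        for i in range(n):
            j = i + tau
            if 0 <= j < n:
                total += x[i] * y[j]
        out.append(0.0 if denom == 0.0 else min(total / denom, 1.0))
    return out


def local_max_oracle(corr):
    """Exhaustive scan for the largest strict interior peak (None if absent)."""
    best = None
    for i in range(1, len(corr) - 1):
        if corr[i] > corr[i - 1] and corr[i] > corr[i + 1]:
            if best is None or corr[i] > best:
                best = corr[i]
    return best


def cci_oracle(int_a, int_b, grid_mz, mass_min, mass_max, width, max_lag):
    """Brute-force CCI: per-interval xcorr local maxima and their product.

    Returns (per_interval_maxima, cci_value, log10cci).
    """
    n_intervals = int(round((mass_max - mass_min) / width))
    maxima = []
    product = 1.0
    absent = False
    for k in range(n_intervals):
        lo = mass_min + k * width
        hi = lo + width
        idx = [i for i, m in enumerate(grid_mz) if lo - 1e-9 <= m < hi - 1e-9]
        x = [int_a[i] for i in idx]
        y = [int_b[i] for i in idx]
        if len(x) < max_lag + 2:
            maxima.append(None)
            absent = True
            continue
        peak = local_max_oracle(xcorr_oracle(x, y, max_lag))
        maxima.append(peak)
        if peak is None or peak <= 0.0:
            absent = True
        else:
            product *= peak
    if absent:
        return maxima, 0.0, float("-inf")
    return maxima, product, math.log10(product) if product > 0 else float("-inf")
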