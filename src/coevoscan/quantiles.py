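"""Package-wide quantile convention.

Every empirical threshold in this package (Tajima's D null percentiles, the
per-bin 99th-percentile r2 thresholds, the chromosome-wide beta top fraction)
uses the same rule: linear interpolation between the closest order
statistics. All outlier/flagging comparisons against these thresholds are
strict inequalities, so ties are never significant.
"""

from __future__ import annotations

import numpy as np


def quantile(values, q: float) -> float:
    """Quantile of ``values`` at fraction ``q`` in [0, 1], linear interpolation."""
    a = np.asarray(values, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("quantile of empty (or all-undefined) value set")
    return float(np.quantile(a, q, method="linear"))


def percentile(values, p: float) -> float:
    """Percentile (``p`` in [0, 100]) under the package convention."""
    return quantile(values, p / 100.0)
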