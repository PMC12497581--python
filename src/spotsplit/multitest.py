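"""Multiple-testing helpers shared by the spatial and bulk statistics."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values (untestable rows) propagate as NaN and do not enter the
    correction.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
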