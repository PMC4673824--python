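"""Order-2 Hill-number diversity and the diversity ratio DR.

The order-2 Hill number D = 1 / sum(p_i^2) is the effective number of
equally frequent variants; it is the reciprocal of the probability that two
randomly drawn copies are identical.  The diversity ratio DR = D_bg / D_f
compares background-genome diversity with focal-locus diversity: DR >> 1
signals a gene-specific (horizontal) sweep, DR ~ 1 a whole-genome
(vertical) sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hill2", "diversity_ratio"]


def hill2(counts) -> float:
    """Order-2 Hill diversity of a composition given as variant counts.

    Zero counts are dropped (only variants present in the community enter
    the proportions).  Counts may be any non-negative numbers; the result
    is invariant under rescaling and permutation.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        c = c.ravel()
    if np.any(c < 0):
        raise ValueError("variant counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("at least one positive count is required")
    p = c / c.sum()
    return float(1.0 / np.dot(p, p))


def diversity_ratio(D_bg: float, D_f: float) -> float:
    """Diversity ratio DR = D_bg / D_f."""
    if D_f <= 0:
        raise ValueError(f"focal diversity must be positive, got {D_f}")
    return D_bg / D_f
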