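"""Independent numerical oracles used by the test suite.

The moment oracle integrates an unnormalized 1-D log-density on a dense grid
(Simpson rule) and returns mean and variance; it never calls the closed-form
conditional-parameter code it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson


def grid_moments(log_density, lo: float, hi: float, n: int = 20001):
    """Mean and variance of exp(log_density) on [lo, hi] by Simpson quadrature."""
    v = np.linspace(lo, hi, n)
    lf = np.array([log_density(x) for x in v])
    w = np.exp(lf - lf.max())
    Z = simpson(w, x=v)
    mean = simpson(w * v, x=v) / Z
    var = simpson(w * (v - mean) ** 2, x=v) / Z
    return mean, var


def rank_auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[truth]
    neg = scores[~truth]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))
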