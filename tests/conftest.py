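"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: sample
entropy by exhaustive pairwise enumeration, coarse-graining by explicit
per-segment recomputation, and the moving-window filter rule applied
index by index.
"""

import math

import numpy as np
import pytest
from hypothesis import settings
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def sampen_bruteforce(x, m, r):
    """O(N^2) exhaustive pair enumeration over the N-m template indices.

    Returns (B, A, value): B = length-m template pairs at Chebyshev
    distance < r, A = the same pairs matching at length m+1,
    value = -ln(A/B) or NaN.
    """
    x = np.asarray(x, dtype=float)
    nt = len(x) - m
    tm = sliding_window_view(x, m)[:nt]
    tm1 = sliding_window_view(x, m + 1)
    iu = np.triu_indices(nt, k=1)
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=-1)[iu]
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=-1)[iu]
    b = int((dm < r).sum())
    a = int((dm1 < r).sum())
    value = -math.log(a / b) if (a > 0 and b > 0) else float("nan")
    return b, a, value


def coarse_bruteforce(x, scale, moment):
    """Per-segment recomputation with an explicit python loop."""
    x = np.asarray(x, dtype=float)
    out = []
    for k in range(len(x) // scale):
        seg = x[k * scale:(k + 1) * scale]
        if moment == "mean":
            out.append(seg.mean())
        elif moment == "variance":
            out.append(seg.var(ddof=1))
        else:
            raise ValueError(moment)
    return np.array(out)


def filter_mask_bruteforce(x, l, a, edges="truncated"):
    """Apply the moving-window exclusion rule independently at every index."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = (l - 1) // 2
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        nbrs = np.concatenate([x[max(0, i - h):i], x[i + 1:min(n, i + h + 1)]])
        if edges == "keep" and len(nbrs) < l - 1:
            continue
        if len(nbrs) < h:
            continue
        m_c = nbrs.mean()
        if x[i] < (1 - a) * m_c or x[i] > (1 + a) * m_c:
            mask[i] = True
    return mask


def gaussian_sampen_closed_form(r, sigma=1.0):
    """SampEn limit for i.i.d. Gaussian noise: -ln(2*Phi(r/(sigma*sqrt(2)))-1).

    For i.i.d. data the per-coordinate match probability factorizes, so
    the conditional probability that an m-template match extends one step
    is the single-coordinate matching probability
    P(|X - Y| < r) = 2*Phi(r/(sigma*sqrt(2))) - 1.
    """
    return -np.log(2 * norm.cdf(r / (sigma * np.sqrt(2))) - 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
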