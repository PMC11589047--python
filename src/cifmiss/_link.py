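"""Complementary log-log link used throughout the package.

The cumulative incidence model is ``g(F1(t|X)) = alpha(t) + beta*X`` with
``g(u) = log(-log(1-u))``; ``h`` is its inverse and ``hprime`` the derivative
of ``h``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["g", "h", "hprime"]


def g(u):
    """cloglog link, mapping (0,1) onto the real line."""
    u = np.asarray(u, dtype=float)
    return np.log(-np.log1p(-u))


def h(u):
    """Inverse cloglog link: h(u) = 1 - exp(-exp(u))."""
    u = np.asarray(u, dtype=float)
    return -np.expm1(-np.exp(u))


def hprime(u):
    """Derivative of h: exp(u) * (1 - h(u)) = exp(u - exp(u))."""
    u = np.asarray(u, dtype=float)
    return np.exp(u - np.exp(u))
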