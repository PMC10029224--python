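"""Mean-precision beta likelihood and boundary handling for proportion data."""

from __future__ import annotations

import numpy as np
from scipy import special


def beta_logpdf(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, all on (0, 1) / (0, inf).

    The mean-precision parametrization: E[y] = mu, Var[y] = mu(1-mu)/(1+phi).
    Boundary y values (0 or 1) are rejected: shrink them first with
    :func:`shrink_boundary`.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1); shrink boundary values first")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
           + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return float(out) if out.ndim == 0 else out


def shrink_boundary(y, n: int):
    """Compress [0, 1] data into (0, 1): (y*(n-1) + 0.5) / n.

    The standard adjustment for beta likelihoods when the proportion can
    attain its bounds (e.g. an FI of exactly 0 in fully robust subjects);
    n is the sample size.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    y = np.asarray(y, dtype=float)
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out
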