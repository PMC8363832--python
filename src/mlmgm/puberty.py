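"""Individual pubertal trajectories: sigmoid growth, timing/tempo draws,
and Tanner-stage coarsening.

Each subject's pubertal status follows a logistic curve

    p(x) = 1 / (1 + exp(-k * (x - z)))

where ``x`` is age in years relative to the sample mean age (12), ``z``
is the trajectory midpoint (the age offset at which p = .5, i.e. pubertal
*timing*) and ``k`` the steepness (*tempo*; the central 2%-98% transition
takes 2*ln(49)/k ~ 7.78/k years).

Timing is truncated-normal, z ~ N(0, location_sd^2) truncated at +/- 3
years; tempo is gamma, k ~ Gamma(shape 10, rate 3), giving a mean
steepness of 10/3 and hence mostly slow transitions (> 2 years).  The two
are coupled through a Gaussian copula with positive correlation so that
early starters (small z) tend to have protracted transitions (small k),
while both marginals are preserved exactly.

Ordinal Tanner stages 1-5 are obtained by cutting p at .05/.35/.65/.95
(intervals closed on the left, so p >= .95 is stage 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

TANNER_CUTPOINTS = (0.05, 0.35, 0.65, 0.95)


@dataclass(frozen=True)
class PubertyDistribution:
    """Population distribution of timing and tempo parameters.

    ``location_sd`` is 1.5 years under high pubertal variability and 0.5
    under low variability; truncation bounds are fixed at +/- 3 years.
    The gamma tempo distribution uses the shape/rate parameterisation.
    """

    location_sd: float = 1.5
    truncation: float = 3.0
    shape_gamma_shape: float = 10.0
    shape_gamma_rate: float = 3.0
    zk_correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.location_sd <= 0:
            raise ValueError("location_sd must be positive")
        if self.shape_gamma_shape <= 0 or self.shape_gamma_rate <= 0:
            raise ValueError("gamma parameters must be positive")
        if not -1 < self.zk_correlation < 1:
            raise ValueError("zk_correlation must be in (-1, 1)")


HIGH_VARIABILITY = PubertyDistribution(location_sd=1.5)
LOW_VARIABILITY = PubertyDistribution(location_sd=0.5)


def draw_puberty_params(n: int, dist: PubertyDistribution, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (z, k) pairs from the coupled timing/tempo distribution.

    Returns
    -------
    z : ndarray
        Midpoints in years relative to mean age, truncated to
        [-truncation, truncation].
    k : ndarray
        Sigmoid steepness values (1/years), strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rho = dist.zk_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    u = stats.norm.cdf(latent)
    lo = stats.norm.cdf(-dist.truncation / dist.location_sd)
    hi = stats.norm.cdf(dist.truncation / dist.location_sd)
    z = stats.norm.ppf(lo + u[:, 0] * (hi - lo)) * dist.location_sd
    k = stats.gamma.ppf(u[:, 1], a=dist.shape_gamma_shape, scale=1.0 / dist.shape_gamma_rate)
    return z, k


def puberty_value(x, z, k):
    """Evaluate the logistic pubertal curve p = 1/(1 + e^{-k(x-z)}).

    Accepts scalars or broadcastable arrays; ``x`` is age relative to the
    sample mean age.  The result lies strictly inside (0, 1) and is
    strictly increasing in ``x`` for k > 0.
    """
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-np.asarray(k, dtype=float) * (x - np.asarray(z, dtype=float))))


def tanner_stage(p):
    """Coarsen continuous pubertal status into ordinal Tanner stages 1-5.

    Cut-points .05/.35/.65/.95, with each interval closed on the left
    (p = .95 maps to stage 5).  ``p`` must lie in the open interval (0, 1).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("puberty values must lie strictly inside (0, 1)")
    stage = 1 + np.searchsorted(np.asarray(TANNER_CUTPOINTS), arr, side="right")
    return stage if arr.ndim else int(stage)


def transition_width(k, lower: float = 0.02, upper: float = 0.98):
    """Years needed to traverse from p = ``lower`` to p = ``upper``."""
    span = np.log(upper / (1 - upper)) - np.log(lower / (1 - lower))
    return span / np.asarray(k, dtype=float)
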