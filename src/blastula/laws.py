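"""Parametric one-dimensional laws (normal / log-normal) and KL divergences.

Log-normal laws are parameterised in log-space throughout: ``Law("lognormal",
mu, sigma)`` is the distribution of ``exp(Z)`` with ``Z ~ N(mu, sigma**2)``.
This makes multiplicative propagation (products of log-normals) additive in
the parameters, mirroring the additive propagation of normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

NORMAL = "normal"
LOGNORMAL = "lognormal"

_FAMILIES = (NORMAL, LOGNORMAL)


@dataclass(frozen=True)
class Law:
    """A parametric law, either ``normal`` or ``lognormal`` (log-space params)."""

    family: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def variance(self) -> float:
        return self.sigma**2

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        z = rng.normal(self.mu, self.sigma, size=size)
        return np.exp(z) if self.family == LOGNORMAL else z

    def mean(self) -> float:
        """Mean on the natural (data) scale."""
        if self.family == NORMAL:
            return self.mu
        return math.exp(self.mu + 0.5 * self.sigma**2)

    def median(self) -> float:
        if self.family == NORMAL:
            return self.mu
        return math.exp(self.mu)

    def pdf(self, x) -> np.ndarray:
        if self.family == NORMAL:
            return stats.norm.pdf(x, self.mu, self.sigma)
        return stats.lognorm.pdf(x, s=self.sigma, scale=math.exp(self.mu))

    def ppf(self, q) -> np.ndarray:
        if self.family == NORMAL:
            return stats.norm.ppf(q, self.mu, self.sigma)
        return stats.lognorm.ppf(q, s=self.sigma, scale=math.exp(self.mu))

    def cdf(self, x) -> np.ndarray:
        if self.family == NORMAL:
            return stats.norm.cdf(x, self.mu, self.sigma)
        return stats.lognorm.cdf(x, s=self.sigma, scale=math.exp(self.mu))


def convolve(p: Law, q: Law) -> Law:
    """Law of the sum (normal) or product (log-normal) of independent variables.

    Normal: N(mu1, s1) + N(mu2, s2) = N(mu1 + mu2, sqrt(s1^2 + s2^2)).
    Log-normal: parameters add identically in log-space.
    """
    if p.family != q.family:
        raise ValueError(f"family mismatch: {p.family} vs {q.family}")
    return Law(p.family, p.mu + q.mu, math.hypot(p.sigma, q.sigma))


def kl_divergence(p: Law, q: Law) -> float:
    """D_KL(p || q) in nats, closed form.

    For two normals: log(sq/sp) + (sp^2 + (mp - mq)^2) / (2 sq^2) - 1/2.
    A log-normal pair reduces to the normal formula on log-space parameters
    (KL is invariant under the common change of variables x -> log x).
    """
    if p.family != q.family:
        raise ValueError(f"family mismatch: {p.family} vs {q.family}")
    if p.sigma <= 0 or q.sigma <= 0:
        raise ValueError("KL divergence requires sigma > 0 on both laws")
    return (
        math.log(q.sigma / p.sigma)
        + (p.sigma**2 + (p.mu - q.mu) ** 2) / (2.0 * q.sigma**2)
        - 0.5
    )


def symmetrised_kl(p: Law, q: Law) -> float:
    """Jeffreys-symmetrised divergence (D_KL(p||q) + D_KL(q||p)) / 2."""
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))
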