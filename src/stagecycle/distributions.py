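"""Cell-cycle-time distributions built from chains of exponential stages.

A cell cycle of mean length ``C`` is decomposed into ``k`` sequential
stages, the residence time in stage ``i`` being exponential with rate
``lambda_i``.  The total cell-cycle time (CCT) is then hypoexponentially
distributed.  Two identifiable special cases are exposed:

* **Erlang** — all ``k`` stages share one rate ``lambda`` (mean ``k/lambda``);
* **exponentially modified Erlang (EME)** — ``k`` equal-rate stages at
  ``lambda_1`` followed by one extra stage at a distinct rate ``lambda_2``,
  i.e. the convolution of an Erlang with an independent exponential.

Because every stage is exponential, any of these CCTs can be simulated
exactly inside a Gillespie stochastic simulation, which is the point of
the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "HypoexpParams",
    "ErlangParams",
    "EMEParams",
    "UnsupportedBranchError",
    "erlang_pdf",
    "eme_pdf",
    "eme_pdf_conv",
    "hypoexp_moments",
    "sample_cct",
]


class UnsupportedBranchError(ValueError):
    """Raised when the closed-form EME density is evaluated outside the
    ``lambda_1 > lambda_2`` branch it is valid on."""


@dataclass(frozen=True)
class HypoexpParams:
    """Ordered per-stage rates ``lambda_1 .. lambda_k`` (1/time) of a
    general hypoexponential CCT."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        if len(rates) < 1:
            raise ValueError("at least one stage rate is required")
        if any(r <= 0 or not np.isfinite(r) for r in rates):
            raise ValueError("all stage rates must be strictly positive and finite")
        object.__setattr__(self, "rates", rates)

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        """Mean CCT, the sum of the stage means ``C = sum 1/lambda_i``."""
        return float(sum(1.0 / r for r in self.rates))

    def to_hypoexp(self) -> "HypoexpParams":
        return self


@dataclass(frozen=True)
class ErlangParams:
    """Equal-rates chain: ``k`` stages all at rate ``rate``; the CCT is
    Erlang with shape ``k`` and scale ``1/rate`` (mean ``C = k/rate``)."""

    k: int
    rate: float

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 1:
            raise ValueError("k must be a positive integer")
        object.__setattr__(self, "k", int(self.k))
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError("rate must be strictly positive and finite")

    @property
    def mean(self) -> float:
        return self.k / self.rate

    def to_hypoexp(self) -> HypoexpParams:
        return HypoexpParams((self.rate,) * self.k)

    @classmethod
    def from_mean(cls, k: int, mean_cct: float) -> "ErlangParams":
        """Erlang chain with ``k`` stages and prescribed mean CCT."""
        return cls(k=k, rate=k / mean_cct)


@dataclass(frozen=True)
class EMEParams:
    """Exponentially modified Erlang: ``k`` equal-rate stages at ``lam1``
    followed by a final stage at ``lam2 != lam1``.

    ``L = lam1 - lam2`` is the rate gap entering the closed-form density;
    the closed form is only evaluated on the ``lam1 > lam2`` branch (the
    branch all reported fits to measured CCT histograms lie on).
    """

    k: int
    lam1: float
    lam2: float

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 1:
            raise ValueError("k must be a positive integer")
        object.__setattr__(self, "k", int(self.k))
        for name in ("lam1", "lam2"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.lam1 == self.lam2:
            raise ValueError(
                "lam1 == lam2 degenerates to an Erlang with k+1 stages; "
                "use ErlangParams instead"
            )

    @property
    def L(self) -> float:
        return self.lam1 - self.lam2

    @property
    def mean(self) -> float:
        return self.k / self.lam1 + 1.0 / self.lam2

    def to_hypoexp(self) -> HypoexpParams:
        return HypoexpParams((self.lam1,) * self.k + (self.lam2,))


CctParams = HypoexpParams | ErlangParams | EMEParams


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def erlang_pdf(t, p: ErlangParams):
    """Erlang density ``lambda^k t^(k-1) e^(-lambda t) / (k-1)!``.

    Scalar in, scalar out; arrays are handled elementwise.  Negative times
    raise rather than silently returning 0, since a negative CCT is a
    caller bug.
    """
    t = _check_time(t)
    out = stats.gamma.pdf(t, a=p.k, scale=1.0 / p.rate)
    return out if out.ndim else float(out)


def eme_pdf(t, p: EMEParams):
    """Closed-form exponentially modified Erlang density.

    ``P(t) = lam2 e^(-lam2 t) (lam1/L)^k * gammainc(k, L t)`` with
    ``L = lam1 - lam2`` and ``gammainc`` the regularized lower incomplete
    gamma function (the regularized form avoids the catastrophic
    cancellation in ``1 - Gamma(k, Lt)/(k-1)!`` at large ``k``).  Valid
    only for ``lam1 > lam2``; the other branch puts a negative argument in
    the incomplete gamma function and must go through the numerical
    convolution :func:`eme_pdf_conv`.
    """
    if p.lam1 <= p.lam2:
        raise UnsupportedBranchError(
            "the closed-form EME density requires lam1 > lam2; "
            "use eme_pdf_conv for the lam1 < lam2 branch"
        )
    t = _check_time(t)
    L = p.L
    # (lam1/L)^k can overflow for lam1 close to lam2 at large k; work in logs.
    log_pref = p.k * (np.log(p.lam1) - np.log(L))
    with np.errstate(divide="ignore"):
        log_tail = np.where(t > 0, np.log(special.gammainc(p.k, L * t)), -np.inf)
    out = np.exp(np.log(p.lam2) - p.lam2 * t + log_pref + log_tail)
    out = np.where(t > 0, out, 0.0)
    return out if out.ndim else float(out)


def eme_pdf_conv(t, p: EMEParams):
    """EME density by direct numerical convolution of the Erlang(k, lam1)
    and exponential(lam2) densities.

    Works on either rate branch; used as the fallback for
    ``lam1 <= lam2`` and as an independent cross-check of :func:`eme_pdf`.
    """
    t = _check_time(t)
    erl = ErlangParams(p.k, p.lam1)

    def one(ti: float) -> float:
        if ti == 0.0:
            return 0.0
        val, _ = integrate.quad(
            lambda s: erlang_pdf(s, erl) * p.lam2 * np.exp(-p.lam2 * (ti - s)),
            0.0,
            ti,
            limit=200,
        )
        return val

    if t.ndim == 0:
        return one(float(t))
    return np.array([one(ti) for ti in t.ravel()]).reshape(t.shape)


def hypoexp_moments(p: CctParams) -> tuple[float, float]:
    """Mean and variance of the CCT.

    The mean is the sum of the stage means and the variance the sum of the
    stage variances: ``sum 1/lambda_i`` and ``sum 1/lambda_i**2``.
    """
    rates = np.asarray(p.to_hypoexp().rates)
    return float(np.sum(1.0 / rates)), float(np.sum(1.0 / rates**2))


def sample_cct(p: CctParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. cell-cycle times.

    Sampling mirrors the stage mechanism exactly — one exponential draw
    per stage, summed — rather than inverting the CDF, so the draws are
    distributed identically to first-division times of the stage chain.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rates = p.to_hypoexp().rates
    total = np.zeros(n)
    for lam in rates:
        total += rng.exponential(scale=1.0 / lam, size=n)
    return total
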