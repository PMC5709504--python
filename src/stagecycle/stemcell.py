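"""Cancer stem-cell proliferation/differentiation with multi-stage cell cycles.

Stem cells S divide at overall rate ``rho_s`` (mean CCT ``1/rho_s``); at
the instant of division a fate is drawn: with probability ``r1`` symmetric
division (S -> S + S), with ``r3`` symmetric differentiation
(S -> P + P, the stem cell is lost), and otherwise asymmetric
self-renewal (S -> S + P).  Progenitors P are inert counters here.

Replacing the single exponential cell-cycle clock with ``k`` Erlang
stages (per-stage rate ``rho_s * k``) keeps the mean CCT but shrinks its
variance; with ``r1 > r3`` the population still grows exponentially, yet
both the growth of mean and variance and the probability of reaching a
given tumour size slow down as ``k`` increases — so the exponential
mean-field law fitted to the k = 1 model overestimates the multi-stage
tumour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distributions import ErlangParams
from .ssa import EnsembleSummary, Fate, StageState, ensemble_summary

__all__ = ["StemCellParams", "simulate_stemcells", "stemcell_mean_field"]


@dataclass(frozen=True)
class StemCellParams:
    """Parameters of the stem-cell model.

    ``rho_s``: division rate (1/time), so the mean CCT is ``1/rho_s``.
    ``r1``/``r3``: probabilities of symmetric division / symmetric
    differentiation; asymmetric self-renewal takes the rest,
    ``r2 = 1 - r1 - r3``.  ``k``: Erlang stages per cycle.  ``s0``:
    initial stem cells (all in stage 1).
    """

    rho_s: float = 1.0
    r1: float = 0.2
    r3: float = 0.15
    k: int = 1
    s0: int = 1
    track_progenitors: bool = False

    def __post_init__(self) -> None:
        if not (self.rho_s > 0 and np.isfinite(self.rho_s)):
            raise ValueError("rho_s must be strictly positive")
        if not (0.0 <= self.r1 <= 1.0 and 0.0 <= self.r3 <= 1.0):
            raise ValueError("r1 and r3 must lie in [0, 1]")
        if self.r1 + self.r3 > 1.0 + 1e-12:
            raise ValueError("r1 + r3 must not exceed 1 (r2 = 1 - r1 - r3 >= 0)")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError("k must be a positive integer")
        object.__setattr__(self, "k", int(self.k))
        if int(self.s0) != self.s0 or self.s0 < 1:
            raise ValueError("s0 must be a positive integer")
        object.__setattr__(self, "s0", int(self.s0))

    @property
    def r2(self) -> float:
        return 1.0 - self.r1 - self.r3

    @property
    def fates(self) -> list[Fate]:
        # (probability, stem daughters restarted in stage 1, progenitors)
        return [(self.r1, 2, 0), (self.r2, 1, 1), (self.r3, 0, 2)]

    @property
    def stage_model(self) -> ErlangParams:
        return ErlangParams(k=self.k, rate=self.rho_s * self.k)


def simulate_stemcells(
    p: StemCellParams,
    t_end: float,
    record_times,
    reps: int,
    seed: int,
    threshold: int | None = 1000,
    keep_totals: bool = False,
) -> EnsembleSummary:
    """Ensemble of exact SSA runs of the stem-cell model.

    Returns mean and variance of the stem count and the first-passage
    probability of the tumour having reached ``threshold`` stem cells by
    each record time; mean progenitor counts are included when
    ``p.track_progenitors`` is set.
    """
    x0 = StageState(counts=(p.s0,) + (0,) * (p.k - 1))
    summary = ensemble_summary(
        reps=reps,
        model=p.stage_model,
        t_end=t_end,
        record_times=record_times,
        seed=seed,
        fates=p.fates,
        x0=x0,
        threshold=threshold,
        keep_totals=keep_totals,
    )
    if not p.track_progenitors:
        summary.mean_progenitors = None
    return summary


def stemcell_mean_field(p: StemCellParams, t) -> np.ndarray:
    """Deterministic mean-field law ``S(t) = S0 exp(rho_s (r1 - r3) t)``,
    the solution of ``dS/dt = rho_s (r1 - r3) S``.

    Exact for the mean only in the single-stage (k = 1) model; with
    k > 1 stages it overestimates the true mean, which is why a warning
    is raised rather than silently extrapolating.
    """
    if p.k > 1:
        warnings.warn(
            "the exponential mean-field law is derived for k = 1; with "
            "k > 1 Erlang stages it overestimates the simulated mean",
            stacklevel=2,
        )
    return p.s0 * np.exp(p.rho_s * (p.r1 - p.r3) * np.asarray(t, dtype=float))
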