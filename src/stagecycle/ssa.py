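"""Exact Gillespie (direct-method) simulation of stage-structured populations.

The state is the vector of cell counts per cell-cycle stage.  Stage-``i``
advance fires with propensity ``lambda_i x_i``; a firing of the final
stage is a division, whose outcome is drawn from a fate table (the plain
chain replaces one final-stage cell with two stage-1 cells; the
stem-cell model plugs in symmetric / asymmetric / differentiating fates).

Two uniforms per event (waiting time from the total propensity, then
linear event selection): statistically exact, no tau-leaping.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .distributions import CctParams, HypoexpParams

__all__ = [
    "StageState",
    "Trajectory",
    "EnsembleSummary",
    "Fate",
    "simulate_chain",
    "simulate_division_process",
    "first_division_times",
    "ensemble_summary",
    "spawn_seeds",
]

#: fate entry: (probability, number of new stage-1 cells, number of progenitors)
Fate = tuple[float, int, int]

#: the ordinary division fate — one final-stage cell becomes two stage-1 cells
DIVISION_FATES: list[Fate] = [(1.0, 2, 0)]


@dataclass(frozen=True)
class StageState:
    """Counts per cell-cycle stage, plus the clock."""

    counts: tuple[int, ...]
    t: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("stage counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def single_cell(cls, k: int) -> "StageState":
        return cls(counts=(1,) + (0,) * (k - 1))


@dataclass
class Trajectory:
    """Stage counts sampled at fixed record times (state of the last
    event at or before each record time)."""

    record_times: np.ndarray
    stage_counts: np.ndarray  # (n_times, n_stages)
    progenitors: np.ndarray | None = None
    first_passage_time: float = np.inf  # first time total >= threshold, if tracked

    @property
    def totals(self) -> np.ndarray:
        return self.stage_counts.sum(axis=1)


@dataclass
class EnsembleSummary:
    """Across-replicate summary of a batch of trajectories.

    ``first_passage_prob`` is the running-maximum reading of "has reached
    the threshold by time t" (tracked at event resolution, so a
    population that touches the threshold and falls back still counts);
    ``at_threshold_prob`` is the alternative "currently at or above"
    reading.
    """

    record_times: np.ndarray
    mean_total: np.ndarray
    var_total: np.ndarray
    first_passage_prob: np.ndarray
    at_threshold_prob: np.ndarray
    mean_stages: np.ndarray
    reps: int
    threshold: int | None = None
    mean_progenitors: np.ndarray | None = None
    totals: np.ndarray | None = None  # per-replicate totals, kept on request


def _as_rates(model: CctParams | tuple | list) -> tuple[float, ...]:
    if hasattr(model, "to_hypoexp"):
        return model.to_hypoexp().rates
    return HypoexpParams(tuple(model)).rates


def _validate_fates(fates: list[Fate]) -> list[Fate]:
    total = sum(p for p, _, _ in fates)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"fate probabilities sum to {total}, not 1")
    return list(fates)


def _run(
    rates: tuple[float, ...],
    fates: list[Fate],
    x0: tuple[int, ...],
    record_times: np.ndarray,
    rng: random.Random,
    threshold: int | None = None,
    stop_after_first_division: bool = False,
) -> Trajectory:
    """Direct-method event loop shared by every non-spatial model."""
    k = len(rates)
    counts = list(x0)
    n_rec = len(record_times)
    snap = np.zeros((n_rec, k), dtype=np.int64)
    prog_snap = np.zeros(n_rec, dtype=np.int64)
    progenitors = 0
    t = 0.0
    rec_i = 0
    total = sum(counts)
    fp_time = 0.0 if (threshold is not None and total >= threshold) else np.inf

    uniform = rng.random
    log = math.log
    inf = math.inf

    # propensities kept incrementally (O(1) per event, O(k) selection);
    # the running total is refreshed periodically to shed float drift
    a = [rates[i] * counts[i] for i in range(k)]
    a0 = sum(a)
    refresh = 0

    while True:
        if a0 <= 0.0:
            t_next = inf
        else:
            t_next = t - log(uniform()) / a0
        # snapshot every record time passed before the next event fires
        while rec_i < n_rec and record_times[rec_i] < t_next:
            snap[rec_i] = counts
            prog_snap[rec_i] = progenitors
            rec_i += 1
        if (rec_i >= n_rec and not stop_after_first_division) or t_next == inf:
            break
        t = t_next
        # linear event selection
        u = uniform() * a0
        i = 0
        acc = a[0]
        while acc < u and i < k - 1:
            i += 1
            acc += a[i]
        if i < k - 1:
            counts[i] -= 1
            counts[i + 1] += 1
            a[i] -= rates[i]
            a[i + 1] += rates[i + 1]
            a0 += rates[i + 1] - rates[i]
        else:
            # division: draw a fate
            counts[k - 1] -= 1
            a[k - 1] -= rates[k - 1]
            a0 -= rates[k - 1]
            uf = uniform()
            cum = 0.0
            for p, n_new, n_prog in fates:
                cum += p
                if uf <= cum:
                    counts[0] += n_new
                    progenitors += n_prog
                    total = total - 1 + n_new
                    a[0] += n_new * rates[0]
                    a0 += n_new * rates[0]
                    break
            if threshold is not None and fp_time == inf and total >= threshold:
                fp_time = t
            if stop_after_first_division:
                while rec_i < n_rec:
                    snap[rec_i] = counts
                    prog_snap[rec_i] = progenitors
                    rec_i += 1
                return Trajectory(record_times, snap, prog_snap, t)
        refresh += 1
        if refresh >= 4096:
            a = [rates[j] * counts[j] for j in range(k)]
            a0 = sum(a)
            refresh = 0

    return Trajectory(record_times, snap, prog_snap, fp_time)


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent per-replicate seeds from a root seed with
    a deterministic counter-based scheme (order-independent)."""
    return np.random.SeedSequence(seed).generate_state(n)


def simulate_chain(
    model: CctParams,
    t_end: float,
    record_times,
    seed: int,
    x0: StageState | None = None,
) -> Trajectory:
    """Exact SSA realisation of the pure-birth stage chain
    ``X_1 -> ... -> X_k -> 2 X_1`` (or its EME variant with the extra
    final stage)."""
    rates = _as_rates(model)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.size and t_end < record_times.max():
        raise ValueError("t_end must cover all record times")
    if x0 is None:
        x0 = StageState.single_cell(len(rates))
    if x0.total < 1:
        raise ValueError("initial state must contain at least one cell")
    if len(x0.counts) != len(rates):
        raise ValueError("initial state and model disagree on stage count")
    return _run(rates, DIVISION_FATES, x0.counts, record_times, random.Random(int(seed)))


def simulate_division_process(
    model: CctParams,
    fates: list[Fate],
    t_end: float,
    record_times,
    seed: int,
    x0: StageState | None = None,
    threshold: int | None = None,
) -> Trajectory:
    """Like :func:`simulate_chain`, but a final-stage firing draws a fate
    from ``fates`` — a list of ``(probability, new stage-1 cells,
    progenitors)`` triples — instead of always producing two daughters."""
    rates = _as_rates(model)
    fates = _validate_fates(fates)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.size and t_end < record_times.max():
        raise ValueError("t_end must cover all record times")
    if x0 is None:
        x0 = StageState.single_cell(len(rates))
    if x0.total < 1:
        raise ValueError("initial state must contain at least one cell")
    return _run(
        rates, fates, x0.counts, record_times, random.Random(int(seed)), threshold
    )


def first_division_times(model: CctParams, reps: int, seed: int) -> np.ndarray:
    """Time of the first division starting from a single stage-1 cell,
    simulated through the event loop.  Distributed as the CCT itself —
    an executable consistency check between the chain simulator and the
    distribution sampler."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rates = _as_rates(model)
    out = np.empty(reps)
    empty = np.array([], dtype=float)
    for i, s in enumerate(spawn_seeds(seed, reps)):
        traj = _run(
            rates,
            DIVISION_FATES,
            StageState.single_cell(len(rates)).counts,
            empty,
            random.Random(int(s)),
            stop_after_first_division=True,
        )
        out[i] = traj.first_passage_time
    return out


def ensemble_summary(
    reps: int,
    model: CctParams,
    t_end: float,
    record_times,
    seed: int,
    fates: list[Fate] | None = None,
    x0: StageState | None = None,
    threshold: int | None = None,
    keep_totals: bool = False,
) -> EnsembleSummary:
    """Run ``reps`` independent replicates and summarise them: mean and
    unbiased variance of the total count, per-stage mean counts, and the
    first-passage fraction for ``threshold`` (if given) at each record
    time.  Per-replicate seeds derive deterministically from ``seed``."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rates = _as_rates(model)
    fates = _validate_fates(fates if fates is not None else DIVISION_FATES)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.size and t_end < record_times.max():
        raise ValueError("t_end must cover all record times")
    if x0 is None:
        x0 = StageState.single_cell(len(rates))

    k = len(rates)
    n_rec = record_times.size
    totals = np.empty((reps, n_rec))
    stage_sum = np.zeros((n_rec, k))
    prog_sum = np.zeros(n_rec)
    fp_times = np.empty(reps)
    at_thresh = np.zeros(n_rec)

    for i, s in enumerate(spawn_seeds(seed, reps)):
        traj = _run(
            rates, fates, x0.counts, record_times, random.Random(int(s)), threshold
        )
        tot = traj.totals
        totals[i] = tot
        stage_sum += traj.stage_counts
        prog_sum += traj.progenitors
        fp_times[i] = traj.first_passage_time
        if threshold is not None:
            at_thresh += tot >= threshold

    mean_total = totals.mean(axis=0)
    var_total = totals.var(axis=0, ddof=1) if reps > 1 else np.zeros(n_rec)
    if threshold is not None:
        fp_prob = (fp_times[:, None] <= record_times[None, :]).mean(axis=0)
        at_prob = at_thresh / reps
    else:
        fp_prob = np.zeros(n_rec)
        at_prob = np.zeros(n_rec)
    return EnsembleSummary(
        record_times=record_times,
        mean_total=mean_total,
        var_total=var_total,
        first_passage_prob=fp_prob,
        at_threshold_prob=at_prob,
        mean_stages=stage_sum / reps,
        reps=reps,
        threshold=threshold,
        mean_progenitors=prog_sum / reps,
        totals=totals if keep_totals else None,
    )
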