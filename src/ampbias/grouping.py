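"""Worst-case differential-diversity analysis over binary sample groupings.

PCR bias can change the apparent separation between groups of samples.  The
distortion is measured by ``delta R^2 = |R^2_35 - R^2_0|``, the absolute
change in a group-difference R^2 between unamplified (cycle-0) and
amplified (cycle-35) data: ANOVA R^2 for scalar alpha-diversity values,
PERMANOVA R^2 for beta-diversity distance matrices.  The worst case is the
binary grouping that maximizes delta R^2, found exactly by brute-force
enumeration for small N, or heuristically by a genetic algorithm or
particle-swarm optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .diversity import DistanceMatrix

__all__ = [
    "GroupingResult",
    "anova_r2",
    "delta_r2",
    "optimize_grouping",
    "permanova_r2",
]


def _as_assignment(assignment, n: int | None = None) -> np.ndarray:
    a = np.asarray(assignment)
    if a.ndim != 1 or not np.all(np.isin(a, (0, 1))):
        raise ValueError("assignment must be a 1-D vector of binary labels")
    if n is not None and a.size != n:
        raise ValueError("assignment length must match the number of samples")
    return a.astype(int)


def anova_r2(values, assignment) -> float:
    """Between-group over total sum of squares for scalar values, in [0, 1]."""
    v = np.asarray(values, dtype=float)
    a = _as_assignment(assignment, v.size)
    if not (np.any(a == 0) and np.any(a == 1)):
        raise ValueError("both groups must be nonempty")
    grand = v.mean()
    sst = float(((v - grand) ** 2).sum())
    if sst == 0.0:
        warnings.warn("zero total variance; ANOVA R^2 defined as 0", stacklevel=2)
        return 0.0
    ssb = sum(np.sum(a == g) * (v[a == g].mean() - grand) ** 2 for g in (0, 1))
    return float(ssb / sst)


def _permanova_ss(d2: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and a binary assignment."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in (0, 1):
        idx = np.flatnonzero(a == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)  # full matrix double-counts i<j
    return float(ss_total), float(ss_within)


def permanova_r2(
    dm: DistanceMatrix, assignment, n_perm: int = 999, seed: int = 0
) -> tuple[float, float, float]:
    """PERMANOVA R^2, pseudo-F and permutation p-value for two groups.

    ``SS_total = sum_{i<j} d_ij^2 / N``; ``SS_within`` sums the analogous
    per-group terms; ``R^2 = 1 - SS_within/SS_total``; pseudo-F uses
    (1, N-2) degrees of freedom.  The p-value permutes group labels and
    counts the observed statistic in both numerator and denominator.
    """
    a = _as_assignment(assignment, dm.N)
    n0, n1 = int(np.sum(a == 0)), int(np.sum(a == 1))
    if n0 < 2 or n1 < 2:
        raise ValueError("PERMANOVA needs at least 2 samples per group")
    d2 = dm.entries**2
    n = dm.N
    ss_total, ss_within = _permanova_ss(d2, a)
    if ss_total == 0.0:
        warnings.warn("zero total sum of squares; PERMANOVA R^2 defined as 0", stacklevel=2)
        return 0.0, 0.0, 1.0
    r2 = 1.0 - ss_within / ss_total
    ss_between = ss_total - ss_within
    f_obs = (ss_between / 1.0) / (ss_within / (n - 2)) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    exceed = 1  # the observed labeling counts
    for _ in range(int(n_perm)):
        perm = rng.permutation(a)
        _, ssw_p = _permanova_ss(d2, perm)
        f_p = ((ss_total - ssw_p) / 1.0) / (ssw_p / (n - 2)) if ssw_p > 0 else np.inf
        if f_p >= f_obs:
            exceed += 1
    p = exceed / (int(n_perm) + 1)
    return float(r2), float(f_obs), float(p)


def _r2(data, assignment, mode: str) -> float:
    if mode == "anova":
        return anova_r2(data, assignment)
    if mode == "permanova":
        a = _as_assignment(assignment)
        d2 = data.entries**2
        ss_total, ss_within = _permanova_ss(d2, a)
        if ss_total == 0.0:
            return 0.0
        return 1.0 - ss_within / ss_total
    raise ValueError(f"unknown mode {mode!r}; use 'anova' or 'permanova'")


def delta_r2(data_cycle0, data_cycle35, assignment, mode: str = "anova") -> float:
    """Absolute change in group-difference R^2 between cycle 0 and cycle 35."""
    r0 = _r2(data_cycle0, assignment, mode)
    r35 = _r2(data_cycle35, assignment, mode)
    return abs(r35 - r0)


@dataclass
class GroupingResult:
    """Best binary grouping found, with its R^2 values at both cycle counts."""

    assignment: np.ndarray
    r2_cycle0: float
    r2_cycle35: float
    delta_r2: float
    method: str
    seed: int

    def __post_init__(self) -> None:
        self.assignment = _as_assignment(self.assignment)
        if abs(self.delta_r2 - abs(self.r2_cycle35 - self.r2_cycle0)) > 1e-12:
            raise ValueError("delta_r2 must equal |r2_cycle35 - r2_cycle0|")
        if not (np.any(self.assignment == 0) and np.any(self.assignment == 1)):
            raise ValueError("both groups must be nonempty")


def _n_samples(data, mode: str) -> int:
    return len(np.asarray(data)) if mode == "anova" else data.N


def _feasible(a: np.ndarray, min_size: int) -> bool:
    s = int(a.sum())
    return min_size <= s <= a.size - min_size


def _repair(a: np.ndarray, min_size: int, rng: np.random.Generator) -> np.ndarray:
    a = a.copy()
    while a.sum() < min_size:
        a[rng.choice(np.flatnonzero(a == 0))] = 1
    while a.size - a.sum() < min_size:
        a[rng.choice(np.flatnonzero(a == 1))] = 0
    return a


def _local_polish(objective, a: np.ndarray, val: float, min_size: int):
    """Greedy ascent over single flips and pairwise exchanges."""
    a, improved = a.copy(), True
    while improved:
        improved = False
        candidates = []
        for i in range(a.size):
            cand = a.copy()
            cand[i] = 1 - cand[i]
            candidates.append(cand)
        if a.size <= 64:
            zeros, ones = np.flatnonzero(a == 0), np.flatnonzero(a == 1)
            for i in zeros:
                for j in ones:
                    cand = a.copy()
                    cand[i], cand[j] = 1, 0
                    candidates.append(cand)
        for cand in candidates:
            if not _feasible(cand, min_size):
                continue
            v = objective(cand)
            if v > val + 1e-15:
                a, val, improved = cand, v, True
                break
    return a, val


def _brute_force(objective, n: int, min_size: int):
    best_val, best_a = -np.inf, None
    # fix sample 0 in group 0 to break the label-swap symmetry
    for code in range(1, 2 ** (n - 1)):
        a = np.zeros(n, dtype=int)
        a[1:] = (code >> np.arange(n - 1)) & 1
        if not _feasible(a, min_size):
            continue
        val = objective(a)
        if val > best_val:
            best_val, best_a = val, a
    return best_a, best_val


def _ga(objective, n: int, min_size: int, rng: np.random.Generator,
        pop_size: int = 50, generations: int = 100, tournament: int = 3,
        crossover_p: float = 0.8):
    pop = [_repair(rng.integers(0, 2, size=n), min_size, rng) for _ in range(pop_size)]
    fit = np.array([objective(a) for a in pop])
    best_i = int(np.argmax(fit))
    best_a, best_val = pop[best_i].copy(), float(fit[best_i])
    for _ in range(generations):
        new_pop = [best_a.copy()]  # elitism
        while len(new_pop) < pop_size:
            picks = rng.integers(0, pop_size, size=(2, tournament))
            p1 = pop[picks[0][np.argmax(fit[picks[0]])]]
            p2 = pop[picks[1][np.argmax(fit[picks[1]])]]
            if rng.random() < crossover_p:
                mask = rng.integers(0, 2, size=n).astype(bool)
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(n) < 1.0 / n
            child = np.where(flip, 1 - child, child)
            new_pop.append(_repair(child, min_size, rng))
        pop = new_pop
        fit = np.array([objective(a) for a in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_val:
            best_a, best_val = pop[gen_best].copy(), float(fit[gen_best])
    return best_a, best_val


def _pso_swarm(objective, n, min_size, rng, n_particles, iterations,
               inertia, c1, c2, vmax):
    pos = rng.random((n_particles, n))
    vel = np.zeros((n_particles, n))
    pbest_pos = pos.copy()
    pbest_val = np.full(n_particles, -np.inf)
    best_a, best_val = None, -np.inf
    for _ in range(iterations + 1):
        for k in range(n_particles):
            a = _repair((pos[k] > 0.5).astype(int), min_size, rng)
            val = objective(a)
            if val > pbest_val[k]:
                pbest_val[k], pbest_pos[k] = val, pos[k].copy()
            if val > best_val:
                best_val, best_a = float(val), a
        gbest_pos = pbest_pos[int(np.argmax(pbest_val))]
        r1, r2_ = rng.random((2, n_particles, n))
        vel = inertia * vel + c1 * r1 * (pbest_pos - pos) + c2 * r2_ * (gbest_pos - pos)
        vel = np.clip(vel, -vmax, vmax)  # keep particles exploring near the 0.5 threshold
        pos = np.clip(pos + vel, 0.0, 1.0)
        # turbulence: occasional coordinate kicks prevent premature consensus
        kick = rng.random((n_particles, n)) < 0.05
        pos = np.where(kick, rng.random((n_particles, n)), pos)
    return best_a, best_val


def _pso(objective, n: int, min_size: int, rng: np.random.Generator,
         n_particles: int = 40, iterations: int = 200,
         inertia: float = 0.72, c1: float = 1.49, c2: float = 1.49,
         vmax: float = 0.25, n_restarts: int = 4):
    # independent swarms: a single swarm's global-best attractor reliably
    # traps it in strong local optima of the rugged delta-R^2 landscape
    best_a, best_val = None, -np.inf
    per = max(1, iterations // n_restarts)
    for _ in range(n_restarts):
        a, val = _pso_swarm(objective, n, min_size, rng, n_particles, per,
                            inertia, c1, c2, vmax)
        if val > best_val:
            best_a, best_val = a, val
    return best_a, best_val


def optimize_grouping(
    data_cycle0,
    data_cycle35,
    mode: str = "anova",
    method: str = "brute_force",
    min_size: int = 2,
    seed: int = 0,
    **options,
) -> GroupingResult:
    """Find the binary grouping maximizing ``|R^2_35 - R^2_0|``.

    ``data_cycle0``/``data_cycle35`` are scalar value arrays (``mode='anova'``)
    or :class:`DistanceMatrix` objects (``mode='permanova'``) over the same
    samples.  ``method`` is ``brute_force`` (exact, enumerates all
    bipartitions), ``ga`` or ``pso`` (seeded heuristics that can never exceed
    the brute-force optimum).  Extra ``options`` are passed to the heuristic.
    """
    n = _n_samples(data_cycle0, mode)
    if _n_samples(data_cycle35, mode) != n:
        raise ValueError("cycle-0 and cycle-35 data must cover the same samples")
    if min_size < 1 or n < 2 * min_size:
        raise ValueError(f"infeasible constraint: need N >= 2*min_size, got N={n}, min_size={min_size}")
    if mode == "permanova" and min_size < 2:
        raise ValueError("PERMANOVA needs min_size >= 2")

    def objective(a):
        return delta_r2(data_cycle0, data_cycle35, a, mode=mode)

    rng = np.random.default_rng(seed)
    if method == "brute_force":
        if n > 24:
            raise ValueError("brute force enumerates 2^(N-1) bipartitions; N > 24 is unsupported")
        best_a, _ = _brute_force(objective, n, min_size)
    elif method == "ga":
        best_a, best_val = _ga(objective, n, min_size, rng, **options)
        best_a, _ = _local_polish(objective, best_a, best_val, min_size)
    elif method == "pso":
        best_a, best_val = _pso(objective, n, min_size, rng, **options)
        best_a, _ = _local_polish(objective, best_a, best_val, min_size)
    else:
        raise ValueError(f"unknown method {method!r}")
    if best_a is None:
        raise ValueError("no feasible grouping exists under the constraints")
    r0 = _r2(data_cycle0, best_a, mode)
    r35 = _r2(data_cycle35, best_a, mode)
    return GroupingResult(best_a, float(r0), float(r35), abs(r35 - r0), method, seed)
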