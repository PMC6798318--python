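"""Infinite-population (replicator / Nagylaki) dynamics and sign inference.

The deterministic frequency update over a fixed genotype support is

    X'(s) = X(s) F(s) / Fbar,     Fbar = sum_s X(s) F(s),

the discrete replicator equation; mean fitness is non-decreasing along every
trajectory (Fisher's theorem), which is asserted at run time.

Persistence of two genotype variants that differ only inside a single
regulation set K_j reveals the sign of the environment coefficient b_j: if
both variants hold frequencies above floors p0 and p1 for longer than the
learning time

    T_c > -log(p0 p1) / (|b_j| delta_j),     delta_j = |f_j(s) - f_j(sbar)|,

then the variant with higher trait expression must be favoured iff b_j > 0.
``infer_sign`` implements that test, refusing on pleiotropic pairs (variants
whose differing genes touch more than one regulation set) or when the trait
expressions do not separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpmap import Environment, TraitModel, fitness, trait_expression

__all__ = [
    "FrequencyState",
    "GenotypePair",
    "ReplicatorTrajectory",
    "InferenceResult",
    "replicator_step",
    "run_replicator",
    "fitness_vector",
    "learning_time_bound",
    "q_ratio_trajectory",
    "infer_sign",
]


@dataclass
class FrequencyState:
    """Frequencies over a fixed genotype support (nonnegative, summing to 1)."""

    support: list
    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if len(self.support) != self.x.shape[0]:
            raise ValueError("support and frequency vector lengths differ")
        if (self.x < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if not np.isclose(self.x.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


@dataclass
class GenotypePair:
    """An ordered genotype pair (s, sbar) with their differing-gene set."""

    s: np.ndarray
    s_bar: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=np.int8)
        self.s_bar = np.asarray(self.s_bar, dtype=np.int8)
        if self.s.shape != self.s_bar.shape:
            raise ValueError("pair genotypes must have equal length")

    @property
    def diff(self) -> np.ndarray:
        """Diff(s, sbar): indices of the genes in which the pair differs."""
        return np.flatnonzero(self.s != self.s_bar)


def fitness_vector(support, model: TraitModel, env: Environment) -> np.ndarray:
    """Fitness of every genotype in the support."""
    return np.array([fitness(s, model, env) for s in support])


def replicator_step(x: np.ndarray, fitnesses: np.ndarray) -> np.ndarray:
    """One replicator update X' = X F / Fbar, renormalized exactly."""
    x = np.asarray(x, dtype=float)
    f = np.asarray(fitnesses, dtype=float)
    if (f <= 0).any():
        raise ValueError("fitnesses must be positive")
    y = x * f
    return y / y.sum()


@dataclass
class ReplicatorTrajectory:
    """Dense frequency trajectory: x[t, i] for genotype i of the support."""

    support: list
    x: np.ndarray  # (T+1, n)
    mean_fitness: np.ndarray  # (T+1,)
    fitnesses: np.ndarray  # (n,)

    def index_of(self, s) -> int:
        key = np.asarray(s, dtype=np.int8).tobytes()
        for i, g in enumerate(self.support):
            if np.asarray(g, dtype=np.int8).tobytes() == key:
                return i
        raise KeyError("genotype not in trajectory support")


def run_replicator(
    state: FrequencyState,
    fitnesses: np.ndarray,
    n_steps: int,
    check_fisher: bool = True,
) -> ReplicatorTrajectory:
    """Iterate the replicator map; asserts Fisher monotonicity of Fbar."""
    f = np.asarray(fitnesses, dtype=float)
    xs = np.empty((n_steps + 1, f.shape[0]))
    xs[0] = state.x
    for t in range(n_steps):
        xs[t + 1] = replicator_step(xs[t], f)
    fbar = xs @ f
    if check_fisher and not (np.diff(fbar) >= -1e-12 * fbar[:-1]).all():
        raise AssertionError("mean fitness decreased along a replicator trajectory")
    return ReplicatorTrajectory(state.support, xs, fbar, f)


def learning_time_bound(p0: float, p1: float, b_j: float, delta_j: float) -> float:
    """Minimal co-persistence time -log(p0 p1) / (|b_j| delta_j).

    Above this time, persistence of both variants at frequencies p0, p1 is
    inconsistent with the selection differential |b_j| delta_j acting against
    one of them.
    """
    if not (0 < p0 <= 1 and 0 < p1 <= 1):
        raise ValueError("p0 and p1 must lie in (0, 1]")
    drive = abs(b_j) * delta_j
    if drive <= 0:
        raise ValueError("|b_j| * delta_j must be positive")
    return -np.log(p0 * p1) / drive


def q_ratio_trajectory(traj: ReplicatorTrajectory, pair: GenotypePair) -> np.ndarray:
    """Frequency ratio Q(t) = X(s, t) / X(sbar, t) along a trajectory.

    Along the replicator flow Q grows (or shrinks) exactly geometrically with
    ratio F(s)/F(sbar), independently of the other genotypes' frequencies.
    """
    i, j = traj.index_of(pair.s), traj.index_of(pair.s_bar)
    denom = traj.x[:, j]
    if (denom == 0).any():
        raise ValueError("X(sbar, t) hit zero; Q undefined")
    return traj.x[:, i] / denom


@dataclass
class InferenceResult:
    """Outcome of a sign-inference attempt."""

    label: str  # "positive" | "negative" | "refuse"
    trait: int | None = None
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.label != "refuse"


def infer_sign(
    pair: GenotypePair,
    model: TraitModel,
    traj: ReplicatorTrajectory,
    p0: float,
    p1: float,
    t_c: int,
) -> InferenceResult:
    """Infer the sign of b_j from co-persistence of a genotype pair.

    Requires Diff(s, sbar) to lie inside exactly one regulation set K_j with
    trait expressions separated (delta_j > 0), and the persistence conditions
    X(s, T1) >= p0 and X(sbar, T1 + t_c) >= p1 at the two endpoints of the
    trajectory's final t_c-step window.  The endpoint (not interval-wide)
    reading is forced: the replicator ratio identity gives
    p0 * p1 <= exp(-|b_j| delta_j t_c) whenever both floors bind at both
    ends, so interval-wide floors can never satisfy the learning-time
    condition.  Returns "positive" when f_j(s) < f_j(sbar), "negative" when
    f_j(s) > f_j(sbar), and a "refuse" with a reason when any hypothesis
    fails.  The caller is responsible for t_c exceeding
    ``learning_time_bound``.
    """
    diff = pair.diff
    if diff.size == 0:
        return InferenceResult("refuse", reason="identical genotypes")
    touched = [
        j for j in range(model.n_traits)
        if np.intersect1d(diff, model.regulation_set(j)).size > 0
    ]
    if len(touched) != 1:
        return InferenceResult(
            "refuse",
            reason=f"differing genes touch {len(touched)} regulation sets",
        )
    j = touched[0]
    if not np.isin(diff, model.regulation_set(j)).all():
        return InferenceResult(
            "refuse", reason="a differing gene lies outside every regulation set"
        )
    f_s = trait_expression(pair.s, model)[j]
    f_sbar = trait_expression(pair.s_bar, model)[j]
    if f_s == f_sbar:
        return InferenceResult("refuse", trait=j, reason="delta_j = 0")
    if traj.x.shape[0] <= t_c:
        return InferenceResult("refuse", trait=j, reason="trajectory shorter than t_c")
    t1 = traj.x.shape[0] - 1 - t_c
    i_s, i_sbar = traj.index_of(pair.s), traj.index_of(pair.s_bar)
    if traj.x[t1, i_s] < p0:
        return InferenceResult("refuse", trait=j, reason="X(s, T1) below p0")
    if traj.x[-1, i_sbar] < p1:
        return InferenceResult(
            "refuse", trait=j, reason="X(sbar, T1 + t_c) below p1"
        )
    return InferenceResult("positive" if f_s < f_sbar else "negative", trait=j)
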