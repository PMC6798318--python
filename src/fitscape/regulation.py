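"""Threshold-feedback learning of the fitness landscape.

An adaptive walk in the strong-selection weak-mutation (SSWM) regime climbs
the fitness landscape by accepting only strictly fitness-increasing genotype
changes.  Periodically a regulatory feedback canalizes one trait: the trait
with the currently largest |S_j| among the active, not-yet-regulated traits
has its threshold driven to -D_h (if S_j > 0, locking expression on) or +D_h
(if S_j < 0, locking it off).  Once |h_j| exceeds every attainable |sum w s|
the trait's expression is invariant to mutations -- the trait is canalized,
and the sign of the lock records what the walk has learned about the sign of
the environment coefficient b_j.

A modular schedule splits the traits into consecutive rounds: during round r
only the traits of block r are eligible for locking, with one feedback event
per block trait spread evenly over the round.  Unregulated traits keep their
small neutral threshold and stay sensitive until their own lock arrives;
optionally (``park_future``) traits of future rounds can instead be parked at
+D_h so they contribute a constant to fitness until their round begins.

Two adaptation measures are provided.  ``adapted_count`` counts traits whose
expression matches the sign of b_j to within a tolerance theta (the reference
walk configurations count a trait as well expressed only when it is within
0.05 of its optimal level); ``robust_adapted_count`` additionally requires
the match to survive every single-gene flip, i.e. the trait must also be
mutationally canalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpmap import (
    Environment,
    TraitModel,
    fitness_potential,
    preactivation,
    random_genotype,
    sigmoid,
    trait_expression,
)

__all__ = [
    "RegulationConfig",
    "LearningState",
    "LearningTrace",
    "WALK_PRESETS",
    "modular_schedule",
    "adapted_count",
    "robust_adapted_count",
    "sswm_step",
    "threshold_feedback",
    "run_learning_experiment",
    "preset_experiment",
]


@dataclass
class RegulationConfig:
    """Parameters of a threshold-regulation learning run.

    n_steps:     length of the adaptive walk.
    rounds:      number of blocks in the modular schedule (1 = all traits at once).
    d_h:         magnitude D_h of a regulated threshold; must exceed the largest
                 attainable |sum_i w_ji s_i| for full canalization.
    delta_t:     steps between threshold-feedback events; by default the
                 feedback budget is spread evenly so every trait of a block is
                 regulated by the end of its round.
    p_flip:      per-gene proposal probability per step (the walk's mutation
                 rate analogue); with ``single_flip`` one uniformly random gene
                 is proposed instead.
    d_s:         minimum |S_j| required before a trait may be locked (0 = none).
    theta:       adaptation threshold on expression, in (0, 1).
    h_neutral:   the small neutral threshold h^(0) of sensitive traits.
    regulate:    False gives the baseline walk with fixed small thresholds.
    park_future: park traits of future rounds at +D_h instead of leaving
                 them sensitive until locked.
    """

    n_steps: int = 20000
    rounds: int = 1
    d_h: float = 20.0
    delta_t: int | None = None
    p_flip: float = 0.01
    single_flip: bool = False
    d_s: float = 0.0
    theta: float = 0.5
    h_neutral: float = 0.0
    regulate: bool = True
    park_future: bool = False
    record_every: int = 500

    def __post_init__(self):
        if not self.d_h > 1:
            raise ValueError("d_h must exceed 1")
        if self.delta_t is not None and self.delta_t < 1:
            raise ValueError("delta_t must be >= 1")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")


@dataclass
class LearningState:
    """Mutable state of a learning run: genotype, thresholds, locks."""

    genotype: np.ndarray
    thresholds: np.ndarray
    regulated: np.ndarray  # bool per trait
    round_index: int = 0
    step: int = 0
    potential: float = 0.0  # cached fitness potential of the current genotype


@dataclass
class LearningTrace:
    """Recorded trajectory of a learning run."""

    records: pd.DataFrame
    state: LearningState
    model: TraitModel
    env: Environment

    @property
    def final_adapted(self) -> int:
        return int(self.records["adapted"].iloc[-1])

    @property
    def final_robust_adapted(self) -> int:
        return int(self.records["robust_adapted"].iloc[-1])


def modular_schedule(n_traits: int, rounds: int) -> list[np.ndarray]:
    """Partition trait indices 0..n_traits-1 into ``rounds`` contiguous blocks.

    The first ``n_traits % rounds`` blocks get the larger size
    ceil(n_traits / rounds), the rest floor(n_traits / rounds).
    """
    if not 1 <= rounds <= n_traits:
        raise ValueError("rounds must lie between 1 and the number of traits")
    base, extra = divmod(n_traits, rounds)
    blocks, start = [], 0
    for r in range(rounds):
        size = base + (1 if r < extra else 0)
        blocks.append(np.arange(start, start + size))
        start += size
    return blocks


def adapted_count(f, env: Environment, theta: float = 0.5) -> int:
    """Number of traits whose expression matches the sign of b_j.

    Trait j counts when b_j > 0 and f_j > theta, or b_j < 0 and
    f_j < 1 - theta (strict inequalities).
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    f = np.asarray(f, dtype=float)
    return int(np.sum((env.b > 0) & (f > theta) | (env.b < 0) & (f < 1 - theta)))


def _adapted_mask(f: np.ndarray, env: Environment, theta: float) -> np.ndarray:
    # f may carry trailing axes (e.g. one column per mutant neighbour)
    b = env.b.reshape(env.b.shape + (1,) * (f.ndim - 1))
    return (b > 0) & (f > theta) | (b < 0) & (f < 1 - theta)


def robust_adapted_count(
    s, model: TraitModel, env: Environment, theta: float = 0.5
) -> int:
    """Traits correctly expressed at ``s`` and at every 1-mutant neighbour.

    A trait counts only when its expression matches the sign of b_j for the
    genotype itself and for all n_genes single-gene flips, i.e. when the
    correct expression is canalized against point mutations.
    """
    s = np.asarray(s)
    s0 = preactivation(s, model)  # (n_traits,)
    # flipping gene i adds w[:, i] * (1 - 2 s_i) to every pre-activation
    delta = model.weights * (1.0 - 2.0 * s.astype(float))[None, :]
    f_self = np.atleast_1d(sigmoid(s0, model.sharpness))
    f_nbr = np.atleast_2d(sigmoid(s0[:, None] + delta, model.sharpness))
    ok = _adapted_mask(f_self, env, theta)
    ok &= _adapted_mask(f_nbr, env, theta).all(axis=1)
    return int(ok.sum())


def sswm_step(
    state: LearningState,
    model: TraitModel,
    env: Environment,
    rng: np.random.Generator,
    p_flip: float = 0.01,
    single_flip: bool = False,
) -> LearningState:
    """One SSWM proposal: flip genes, accept iff fitness strictly increases.

    Proposals flip each gene independently with probability ``p_flip``
    (or exactly one uniformly random gene with ``single_flip``).  Ties and
    deleterious proposals are rejected; the state is mutated in place and
    returned.  ``state.thresholds`` overrides the model's thresholds.
    """
    work = TraitModel(model.weights, state.thresholds, model.sharpness)
    if single_flip:
        mask = np.zeros(model.n_genes, dtype=bool)
        mask[rng.integers(model.n_genes)] = True
    else:
        mask = rng.random(model.n_genes) < p_flip
    state.step += 1
    if not mask.any():
        return state
    candidate = state.genotype.copy()
    candidate[mask] = 1 - candidate[mask]
    w_new = fitness_potential(candidate, work, env)
    if w_new > state.potential:
        state.genotype = candidate
        state.potential = w_new
    return state


def threshold_feedback(
    state: LearningState,
    model: TraitModel,
    active: np.ndarray | None = None,
    d_h: float = 20.0,
    d_s: float = 0.0,
) -> LearningState:
    """Lock the threshold of the most strongly driven active trait.

    Among the not-yet-regulated traits in ``active`` (all traits if None),
    pick the one with maximal |S_j| (lowest index on ties).  If S_j > 0 set
    h_j = -D_h (expression locked on); if S_j < 0 set h_j = +D_h (locked
    off); with S_j == 0 the trait is parked at +D_h, matching the step
    sigmoid's tie-break toward zero expression.  A gate ``d_s`` > 0 skips the
    update when |S_j| <= d_s.  No eligible trait -> no-op.
    """
    work = TraitModel(model.weights, state.thresholds, model.sharpness)
    S = preactivation(state.genotype, work)
    eligible = ~state.regulated
    if active is not None:
        sel = np.zeros(model.n_traits, dtype=bool)
        sel[np.asarray(active)] = True
        eligible &= sel
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return state
    j = idx[np.argmax(np.abs(S[idx]))]
    if d_s > 0 and abs(S[j]) <= d_s:
        return state
    state.thresholds[j] = -d_h if S[j] > 0 else d_h
    state.regulated[j] = True
    return state


def _feedback_steps(t0: int, t1: int, n_events: int) -> set[int]:
    # n_events feedback times spread over [t0, t1), end-aligned so the last
    # lock lands on the final step of the round
    if n_events <= 0 or t1 <= t0:
        return set()
    length = t1 - t0
    return {t0 + (length * (k + 1)) // n_events - 1 for k in range(n_events)}


def run_learning_experiment(
    model: TraitModel,
    env: Environment,
    cfg: RegulationConfig,
    rng=None,
    s0: np.ndarray | None = None,
) -> LearningTrace:
    """Run an SSWM walk with (or without) modular threshold regulation.

    Returns a trace recording, every ``cfg.record_every`` steps and at the
    end, the step index, the plain and robust adapted-trait counts, the
    fitness potential, and the number of regulated traits.
    """
    rng = np.random.default_rng(rng)
    if s0 is None:
        s0 = random_genotype(model.n_genes, rng)
    blocks = modular_schedule(model.n_traits, cfg.rounds)
    thresholds = np.full(model.n_traits, cfg.h_neutral, dtype=float)
    if cfg.regulate and cfg.park_future:
        thresholds[:] = cfg.d_h
        thresholds[blocks[0]] = cfg.h_neutral
    state = LearningState(
        genotype=np.asarray(s0, dtype=np.int8).copy(),
        thresholds=thresholds,
        regulated=np.zeros(model.n_traits, dtype=bool),
    )
    work = TraitModel(model.weights, state.thresholds, model.sharpness)
    state.potential = fitness_potential(state.genotype, work, env)

    round_bounds = np.linspace(0, cfg.n_steps, cfg.rounds + 1).astype(int)
    records = []

    def record():
        f = trait_expression(state.genotype, work)
        records.append(
            {
                "step": state.step,
                "adapted": adapted_count(f, env, cfg.theta),
                "robust_adapted": robust_adapted_count(
                    state.genotype, work, env, cfg.theta
                ),
                "potential": state.potential,
                "n_regulated": int(state.regulated.sum()),
                "round": state.round_index,
            }
        )

    record()
    for r, block in enumerate(blocks if cfg.regulate else [np.arange(model.n_traits)]):
        if cfg.regulate:
            t0, t1 = round_bounds[r], round_bounds[r + 1]
            state.round_index = r
            if cfg.park_future:
                # wake the block up: unregulated block traits become sensitive
                state.thresholds[block[~state.regulated[block]]] = cfg.h_neutral
                state.potential = fitness_potential(state.genotype, work, env)
            if cfg.delta_t is None:
                feedback_at = _feedback_steps(t0, t1, block.size)
            else:
                feedback_at = {
                    t for t in range(t0, t1) if (t - t0 + 1) % cfg.delta_t == 0
                }
        else:
            t0, t1 = 0, cfg.n_steps
            feedback_at = set()
        for t in range(t0, t1):
            sswm_step(state, model, env, rng, cfg.p_flip, cfg.single_flip)
            if t in feedback_at:
                threshold_feedback(state, model, block, cfg.d_h, cfg.d_s)
                state.potential = fitness_potential(state.genotype, work, env)
            if state.step % cfg.record_every == 0:
                record()
        if cfg.regulate and cfg.park_future:
            # a parked round may not end with sensitive leftovers: lock any
            # block trait the d_s gate skipped before moving on
            while not state.regulated[block].all():
                n_before = state.regulated.sum()
                threshold_feedback(state, model, block, cfg.d_h, 0.0)
                if state.regulated.sum() == n_before:
                    break
            state.potential = fitness_potential(state.genotype, work, env)
    if not records or records[-1]["step"] != state.step:
        record()
    return LearningTrace(pd.DataFrame.from_records(records), state, work, env)


# ---------------------------------------------------------------------------
# reference walk configurations

#: The two published walk configurations.  "pleiotropy" is the extreme
#: regime of 10 genes controlling 200 traits (about 100 traits per gene);
#: "canalization" is the milder 50-gene, 300-trait setting used to contrast
#: regulated and unregulated evolution.  Both use per-trait in-degree K,
#: standard-normal nonzero weights, b_j = +1 with probability 0.8 (else -1),
#: a random Bernoulli(1/2) initial genome, per-gene proposal rate 0.01, and
#: 20000 walk steps.  Expression uses a unit-sharpness logistic, and a trait
#: counts as correctly adapted when its expression is within 0.05 of its
#: optimal level (theta = 0.95).
WALK_PRESETS: dict[str, dict] = {
    "pleiotropy": dict(n_genes=10, n_traits=200, k=5, p_plus=0.8,
                       n_steps=20000, p_flip=0.01, sharpness=1.0, theta=0.95),
    "canalization": dict(n_genes=50, n_traits=300, k=4, p_plus=0.8,
                         n_steps=20000, p_flip=0.01, sharpness=1.0, theta=0.95),
}


def preset_experiment(
    preset: str,
    rounds: int = 1,
    regulate: bool = True,
    rng=None,
    **overrides,
) -> LearningTrace:
    """Run one replicate of a reference walk configuration.

    Draws a fresh random model, environment and initial genome from ``rng``
    and runs the SSWM walk with (or without) threshold regulation.
    ``overrides`` replace preset entries (e.g. ``n_steps`` for a shorter
    walk).
    """
    from .gpmap import random_environment, random_model_fixed_degree

    if preset not in WALK_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(WALK_PRESETS)}")
    params = {**WALK_PRESETS[preset], **overrides}
    rng = np.random.default_rng(rng)
    model = random_model_fixed_degree(
        params["n_genes"], params["n_traits"], params["k"],
        weight_law="normal", rng=rng, h0=0.0, sharpness=params["sharpness"],
    )
    env = random_environment(params["n_traits"], params["p_plus"], 1.0, rng)
    cfg = RegulationConfig(
        n_steps=params["n_steps"],
        rounds=rounds,
        regulate=regulate,
        p_flip=params["p_flip"],
        theta=params["theta"],
        record_every=params.get("record_every", max(1, params["n_steps"] // 40)),
    )
    return run_learning_experiment(model, env, cfg, rng)
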