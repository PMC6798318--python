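"""Genotype -> trait -> fitness map.

A genotype is a fixed-length 0/1 vector ``s`` (gene i active iff ``s[i] == 1``).
Each quantitative trait ``f_j`` in (0, 1) is a sigmoid of a weighted gene sum
minus a threshold,

    f_j(s) = sigma( sum_i w_ji s_i - h_j ),

so the nonzero entries of row j of the weight matrix W define the regulation
set K_j of the trait.  Fitness couples the trait vector to an environment
vector b through the exponential of a linear potential,

    F(s) = K_F * exp( sum_j b_j f_j(s) ).

Random models draw each weight independently nonzero with probability
beta / N_g (sign symmetric), which makes the per-trait in-degree n_j
Binomial(N_g, beta/N_g); a fixed in-degree generator (exactly K regulators
per trait) is also provided for the adaptive-walk experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "STEP",
    "TraitModel",
    "Environment",
    "sigmoid",
    "preactivation",
    "trait_expression",
    "fitness",
    "fitness_potential",
    "random_model",
    "random_model_fixed_degree",
    "random_genotype",
    "random_environment",
    "pleiotropy_degree_distribution",
    "genotype_to_string",
    "genotype_from_string",
    "save_model",
    "load_model",
    "save_environment",
    "load_environment",
]

#: Sentinel selecting the step-function limit of the sigmoid (infinite sharpness).
STEP = "step"


def _as_genotype(s) -> np.ndarray:
    s = np.asarray(s)
    if s.ndim != 1:
        raise ValueError("genotype must be a 1-d vector")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("genotype entries must be 0 or 1")
    return s.astype(np.int8, copy=False)


def sigmoid(z, sharpness=1.0):
    """Logistic squashing 1 / (1 + exp(-sharpness * z)), or its step limit.

    With ``sharpness=STEP`` returns 1 for z > 0 and 0 for z <= 0; the value 0
    at z == 0 keeps the K-SAT threshold construction exact (ties break low).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite pre-activation")
    if isinstance(sharpness, str):
        if sharpness != STEP:
            raise ValueError(f"unknown sharpness sentinel {sharpness!r}")
        out = (z > 0).astype(float)
    else:
        if not (sharpness > 0 and np.isfinite(sharpness)):
            raise ValueError("sharpness must be positive and finite")
        out = expit(sharpness * z)
    return out if out.ndim else float(out)


@dataclass
class TraitModel:
    """Weight matrix, thresholds and sigmoid sharpness of the trait map.

    ``weights`` has shape (n_traits, n_genes); ``thresholds`` has length
    n_traits.  ``sharpness`` is a positive float or the ``STEP`` sentinel.
    """

    weights: np.ndarray
    thresholds: np.ndarray
    sharpness: float | str = STEP

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-d matrix")
        if self.thresholds.shape != (self.weights.shape[0],):
            raise ValueError("thresholds length must equal the number of traits")
        # validate the sharpness value eagerly
        sigmoid(0.0, self.sharpness)

    @property
    def n_traits(self) -> int:
        return self.weights.shape[0]

    @property
    def n_genes(self) -> int:
        return self.weights.shape[1]

    def regulation_set(self, j: int) -> np.ndarray:
        """Indices of the genes with nonzero weight on trait j (the set K_j)."""
        return np.flatnonzero(self.weights[j])

    def in_degrees(self) -> np.ndarray:
        """Per-trait regulation-set sizes n_j."""
        return np.count_nonzero(self.weights, axis=1)

    def copy(self) -> "TraitModel":
        return replace(
            self, weights=self.weights.copy(), thresholds=self.thresholds.copy()
        )


@dataclass
class Environment:
    """Trait coefficients b and the fitness scale K_F."""

    b: np.ndarray
    K_F: float = 1.0

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if not self.K_F > 0:
            raise ValueError("K_F must be positive")

    @property
    def n_traits(self) -> int:
        return self.b.shape[0]

    @property
    def positive_set(self) -> np.ndarray:
        """Traits whose expression increases fitness (b_j > 0)."""
        return np.flatnonzero(self.b > 0)

    @property
    def negative_set(self) -> np.ndarray:
        """Traits whose expression decreases fitness (b_j < 0)."""
        return np.flatnonzero(self.b < 0)


def preactivation(s, model: TraitModel) -> np.ndarray:
    """Pre-sigmoid trait inputs S_j = sum_i w_ji s_i - h_j."""
    s = _as_genotype(s)
    if s.shape[0] != model.n_genes:
        raise ValueError(
            f"genotype length {s.shape[0]} != model gene count {model.n_genes}"
        )
    return model.weights @ s.astype(float) - model.thresholds


def trait_expression(s, model: TraitModel) -> np.ndarray:
    """Trait expression vector f(s), each component in [0, 1]."""
    return np.atleast_1d(sigmoid(preactivation(s, model), model.sharpness))


def fitness_potential(s, model: TraitModel, env: Environment) -> float:
    """Linear potential W(s, b) = sum_j b_j f_j(s)."""
    if env.n_traits != model.n_traits:
        raise ValueError("environment and model disagree on trait count")
    return float(env.b @ trait_expression(s, model))


def fitness(s, model: TraitModel, env: Environment) -> float:
    """Absolute fitness F(s) = K_F * exp(W(s, b)); always positive."""
    return env.K_F * float(np.exp(fitness_potential(s, model, env)))


# ---------------------------------------------------------------------------
# random model generation


def _nonzero_magnitudes(shape, weight_law: str, rng: np.random.Generator):
    if weight_law == "normal":
        return np.abs(rng.standard_normal(shape))
    if weight_law == "pm1":
        return np.ones(shape)
    raise ValueError("weight_law must be 'normal' or 'pm1'")


def random_model(
    n_genes: int,
    n_traits: int,
    beta: float,
    weight_law: str = "normal",
    rng=None,
    h0: float = 0.0,
    sharpness: float | str = STEP,
    gamma: float = 1.0,
) -> TraitModel:
    """Random sparse trait model: each weight nonzero with probability beta/n_genes.

    Positive and negative weights are equally likely (beta / 2 n_genes each);
    nonzero magnitudes are |standard normal| (``weight_law='normal'``) or 1
    (``'pm1'``), optionally scaled by the global factor ``gamma``.  Thresholds
    start at the constant ``h0``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta > n_genes / 2:
        raise ValueError("beta may not exceed n_genes / 2 (per-sign probability cap)")
    rng = np.random.default_rng(rng)
    u = rng.random((n_traits, n_genes))
    p = beta / (2 * n_genes)
    signs = np.where(u < p, 1.0, np.where(u < 2 * p, -1.0, 0.0))
    w = gamma * signs * _nonzero_magnitudes((n_traits, n_genes), weight_law, rng)
    return TraitModel(w, np.full(n_traits, float(h0)), sharpness)


def random_model_fixed_degree(
    n_genes: int,
    n_traits: int,
    k: int,
    weight_law: str = "normal",
    rng=None,
    h0: float = 0.0,
    sharpness: float | str = STEP,
    gamma: float = 1.0,
) -> TraitModel:
    """Random trait model with exactly ``k`` regulators per trait.

    The k genes of each regulation set are drawn uniformly without
    replacement; nonzero weights are standard normal (``'normal'``) or a
    random sign (``'pm1'``).
    """
    if not 1 <= k <= n_genes:
        raise ValueError("k must be between 1 and n_genes")
    rng = np.random.default_rng(rng)
    w = np.zeros((n_traits, n_genes))
    cols = np.argsort(rng.random((n_traits, n_genes)), axis=1)[:, :k]
    rows = np.repeat(np.arange(n_traits), k)
    if weight_law == "normal":
        vals = rng.standard_normal(n_traits * k)
    elif weight_law == "pm1":
        vals = rng.choice([-1.0, 1.0], size=n_traits * k)
    else:
        raise ValueError("weight_law must be 'normal' or 'pm1'")
    w[rows, cols.ravel()] = gamma * vals
    return TraitModel(w, np.full(n_traits, float(h0)), sharpness)


def random_genotype(n_genes: int, rng=None, p_on: float = 0.5) -> np.ndarray:
    """Random genotype with independent Bernoulli(p_on) bits."""
    rng = np.random.default_rng(rng)
    return (rng.random(n_genes) < p_on).astype(np.int8)


def random_environment(
    n_traits: int, p_plus: float = 0.8, K_F: float = 1.0, rng=None
) -> Environment:
    """Environment with b_j = +1 with probability p_plus, else -1."""
    rng = np.random.default_rng(rng)
    b = np.where(rng.random(n_traits) < p_plus, 1.0, -1.0)
    return Environment(b, K_F)


def pleiotropy_degree_distribution(model: TraitModel) -> np.ndarray:
    """Histogram of per-gene pleiotropy degrees.

    The degree of gene i is the number of traits it regulates,
    |{j : w_ji != 0}|; entry d of the returned array counts the genes of
    degree d.
    """
    degrees = np.count_nonzero(model.weights, axis=0)
    return np.bincount(degrees, minlength=1)


# ---------------------------------------------------------------------------
# plain-text serialization

def genotype_to_string(s) -> str:
    return "".join(str(int(b)) for b in _as_genotype(s))


def genotype_from_string(text: str) -> np.ndarray:
    text = text.strip()
    if not text or set(text) - {"0", "1"}:
        raise ValueError("genotype string must be nonempty over {0,1}")
    return np.fromiter((int(c) for c in text), dtype=np.int8, count=len(text))


def model_to_dict(model: TraitModel) -> dict:
    return {
        "n_traits": model.n_traits,
        "n_genes": model.n_genes,
        "weights": model.weights.ravel().tolist(),  # row-major
        "thresholds": model.thresholds.tolist(),
        "sharpness": model.sharpness,
    }


def model_from_dict(d: dict) -> TraitModel:
    w = np.asarray(d["weights"], dtype=float).reshape(d["n_traits"], d["n_genes"])
    return TraitModel(w, np.asarray(d["thresholds"], dtype=float), d["sharpness"])


def save_model(model: TraitModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> TraitModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_environment(env: Environment, path) -> None:
    with open(path, "w") as fh:
        json.dump({"b": env.b.tolist(), "K_F": env.K_F}, fh)


def load_environment(path) -> Environment:
    with open(path) as fh:
        d = json.load(fh)
    return Environment(np.asarray(d["b"], dtype=float), d["K_F"])
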