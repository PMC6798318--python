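"""Adaptation as Boolean satisfiability.

With ternary weights w_ji in {1, 0, -1}, the step-sigmoid trait map turns
into a clause: choosing the threshold

    h_j = -C_j + 0.5,    C_j = #{i : w_ji = -1},

makes f_j(s) = 1 exactly when the disjunction of literals {s_i : w_ji = 1}
and {NOT s_i : w_ji = -1} is satisfied.  Maximizing fitness with all b_j > 0
is then exactly the K-SAT instance whose clause j collects the regulation set
of trait j.  Random K-SAT has critical clause densities alpha = N_b / N_g:
solutions form a single-flip-connected giant cluster below
alpha_g(K) ~ 2^K ln(K)/K and exist below alpha_c(K) ~ 2^K ln 2; the cluster
structure mirrors a fitness landscape of peaks joined by ridges.

This module provides the construction, a desk-scale brute-force oracle,
solution-graph statistics, and DIMACS CNF import/export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .gpmap import STEP, Environment, TraitModel, fitness, trait_expression

__all__ = [
    "KSATInstance",
    "SolutionGraphStats",
    "model_to_ksat",
    "ksat_to_model",
    "random_ksat",
    "evaluate_clauses",
    "brute_force",
    "equivalence_check",
    "critical_alphas",
    "solution_graph",
    "write_dimacs",
    "read_dimacs",
]

#: brute-force enumeration refuses instances above this variable count
DEFAULT_BRUTE_FORCE_CAP = 20


@dataclass
class KSATInstance:
    """A CNF formula: clauses of signed 1-based literals over n_vars variables."""

    n_vars: int
    clauses: list[tuple[int, ...]]

    def __post_init__(self):
        self.clauses = [tuple(int(l) for l in c) for c in self.clauses]
        for c in self.clauses:
            if len(c) == 0:
                raise ValueError("empty clause")
            for lit in c:
                if lit == 0 or abs(lit) > self.n_vars:
                    raise ValueError(f"literal {lit} out of range 1..{self.n_vars}")

    @property
    def n_clauses(self) -> int:
        return len(self.clauses)

    def clause_lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.clauses], dtype=int)


def model_to_ksat(model: TraitModel) -> KSATInstance:
    """Convert a ternary-weight trait model into its K-SAT instance.

    Clause j carries literal +i for w_ji = 1 and -i for w_ji = -1 (1-based).
    The model's thresholds are overwritten in place with h_j = -C_j + 0.5 so
    that under the step sigmoid f_j(s) = 1 iff clause j is satisfied.
    """
    w = model.weights
    if not np.isin(w, (-1.0, 0.0, 1.0)).all():
        raise ValueError("model weights must be ternary (-1, 0, 1)")
    clauses = []
    for j in range(model.n_traits):
        row = w[j]
        lits = tuple(
            int(np.sign(row[i]) * (i + 1)) for i in np.flatnonzero(row)
        )
        if not lits:
            raise ValueError(f"trait {j} has an empty regulation set")
        clauses.append(lits)
        model.thresholds[j] = -np.count_nonzero(row == -1) + 0.5
    return KSATInstance(model.n_genes, clauses)


def ksat_to_model(instance: KSATInstance) -> TraitModel:
    """Step-sigmoid trait model whose traits are the instance's clauses."""
    w = np.zeros((instance.n_clauses, instance.n_vars))
    h = np.empty(instance.n_clauses)
    for j, clause in enumerate(instance.clauses):
        for lit in clause:
            w[j, abs(lit) - 1] = np.sign(lit)
        h[j] = -sum(1 for lit in clause if lit < 0) + 0.5
    return TraitModel(w, h, STEP)


def random_ksat(
    n_vars: int, n_clauses: int, k: int, rng=None
) -> KSATInstance:
    """Uniform random K-SAT: k distinct variables per clause, random signs."""
    if not 1 <= k <= n_vars:
        raise ValueError("k must lie between 1 and n_vars")
    rng = np.random.default_rng(rng)
    clauses = []
    for _ in range(n_clauses):
        vars_ = rng.choice(n_vars, size=k, replace=False) + 1
        signs = rng.choice([-1, 1], size=k)
        clauses.append(tuple(int(v * s) for v, s in zip(vars_, signs)))
    return KSATInstance(n_vars, clauses)


def evaluate_clauses(instance: KSATInstance, assignments: np.ndarray) -> np.ndarray:
    """Boolean matrix: entry (a, j) is True iff clause j holds for row a."""
    assignments = np.atleast_2d(np.asarray(assignments, dtype=np.int8))
    out = np.zeros((assignments.shape[0], instance.n_clauses), dtype=bool)
    for j, clause in enumerate(instance.clauses):
        sat = np.zeros(assignments.shape[0], dtype=bool)
        for lit in clause:
            col = assignments[:, abs(lit) - 1]
            sat |= (col == 1) if lit > 0 else (col == 0)
        out[:, j] = sat
    return out


def _all_assignments(n_vars: int) -> np.ndarray:
    idx = np.arange(2**n_vars, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n_vars)) & 1).astype(np.int8)


def brute_force(
    instance: KSATInstance, cap: int = DEFAULT_BRUTE_FORCE_CAP
) -> np.ndarray:
    """All satisfying assignments by exhaustive enumeration (rows of a matrix)."""
    if instance.n_vars > cap:
        raise ValueError(f"{instance.n_vars} variables exceed brute-force cap {cap}")
    assignments = _all_assignments(instance.n_vars)
    sat = evaluate_clauses(instance, assignments).all(axis=1)
    return assignments[sat]


def equivalence_check(
    model: TraitModel,
    env: Environment,
    s,
    cap: int = DEFAULT_BRUTE_FORCE_CAP,
) -> tuple[bool, bool, bool]:
    """(all_clauses_sat, all_traits_one, fitness_is_max) for genotype ``s``.

    The model must be K-SAT-constructed (ternary weights, thresholds already
    set) and the environment all-positive, so the three booleans must agree
    whenever the instance is satisfiable.  ``fitness_is_max`` is decided by
    exhaustive search over all genotypes.
    """
    if (env.b <= 0).any():
        raise ValueError("equivalence check requires all b_j > 0")
    if model.n_genes > cap:
        raise ValueError(f"{model.n_genes} genes exceed brute-force cap {cap}")
    work = model.copy()
    instance = model_to_ksat(work)
    s = np.asarray(s, dtype=np.int8)
    all_sat = bool(evaluate_clauses(instance, s[None, :]).all())
    all_one = bool((trait_expression(s, work) == 1.0).all())
    fits = np.array(
        [fitness(a, work, env) for a in _all_assignments(model.n_genes)]
    )
    fitness_is_max = bool(np.isclose(fitness(s, work, env), fits.max()))
    return all_sat, all_one, fitness_is_max


def critical_alphas(k: int) -> tuple[float, float]:
    """Large-K clustering and satisfiability thresholds (alpha_g, alpha_c).

    alpha_g(K) ~ 2^K ln(K)/K bounds the single-flip-connected giant solution
    cluster; alpha_c(K) ~ 2^K ln 2 bounds satisfiability.  Natural logs.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    return (2.0**k) * np.log(k) / k, (2.0**k) * np.log(2.0)


@dataclass
class SolutionGraphStats:
    """Component structure of the single-flip solution graph."""

    n_solutions: int
    n_components: int
    component_sizes: list[int]
    graph: nx.Graph


def solution_graph(
    instance: KSATInstance, cap: int = DEFAULT_BRUTE_FORCE_CAP
) -> SolutionGraphStats:
    """Graph of satisfying assignments, adjacent iff at Hamming distance 1.

    Components give the landscape picture: peaks (solutions) joined by
    single-flip ridges; a single giant component means the whole solution set
    is reachable by pointed mutations.
    """
    sols = brute_force(instance, cap)
    g = nx.Graph()
    keys = [tuple(int(v) for v in row) for row in sols]
    g.add_nodes_from(keys)
    for a in keys:
        for i in range(instance.n_vars):
            b = a[:i] + (1 - a[i],) + a[i + 1 :]
            if b in g and not g.has_edge(a, b):
                g.add_edge(a, b)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return SolutionGraphStats(len(keys), len(sizes), sizes, g)


# ---------------------------------------------------------------------------
# DIMACS CNF

def write_dimacs(instance: KSATInstance, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"p cnf {instance.n_vars} {instance.n_clauses}\n")
        for clause in instance.clauses:
            fh.write(" ".join(str(l) for l in clause) + " 0\n")


def read_dimacs(path) -> KSATInstance:
    n_vars = None
    clauses = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("c"):
                continue
            if line.startswith("p"):
                parts = line.split()
                if len(parts) != 4 or parts[1] != "cnf":
                    raise ValueError(f"malformed problem line: {line!r}")
                n_vars = int(parts[2])
                continue
            lits = [int(tok) for tok in line.split()]
            if lits[-1] != 0:
                raise ValueError("clause line must end with 0")
            clauses.append(tuple(lits[:-1]))
    if n_vars is None:
        raise ValueError("missing 'p cnf' header")
    return KSATInstance(n_vars, clauses)
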