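"""Concentration bounds for the capped-population dynamics, with Monte-Carlo
validation helpers.

The accuracy of the deterministic replicator limit for a finite capped
population rests on a handful of closed-form tail bounds: a Chernoff bound
for sums of Poisson offspring numbers (rate function d), a Bernoulli
lower-half bound (rate function g), the Chernoff-Hoeffding bound through the
Kullback-Leibler divergence D, and Hoeffding's inequality.  Combining them
yields the probability that a co-persistence sign test on a pair of genotype
variants gives a false positive in a population of size N_popmax with
per-gene mutation rate p_mut: the full expression is a sum of six exponential
terms (q_1 .. q_5 and q-tilde), dominated as p_mut -> 0, N_popmax -> oo by

    rho(p) = exp(-(ln 2 - 1/2) p_mut c_F p kappa N_popmax),

and the sign test succeeds with probability at least
(1 - rho(p0) - rho(p1))^T_c.

Every bound here is a plain function of its parameters; the mc_* helpers
estimate the corresponding empirical tail frequencies so tests can check
domination.  Out-of-regime parameter combinations are flagged, not raised,
so sweeps can map the regime boundary.  All logs are natural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BoundParams",
    "Flagged",
    "chernoff_d",
    "poisson_sum_tails",
    "bernoulli_half_g",
    "bernoulli_half_bound",
    "kl_div",
    "hoeffding_bound",
    "u_rate",
    "mutation_rate_exponents",
    "epsilon0",
    "epsilon_tilde",
    "rho",
    "sign_test_probability",
    "q_functions",
    "mc_poisson_sum_tails",
    "mc_bernoulli_half",
    "mc_hoeffding_tail",
    "bounds_report",
]


class Flagged(NamedTuple):
    """A numeric result plus a validity flag for its asymptotic regime."""

    value: float
    in_regime: bool


@dataclass
class BoundParams:
    """Parameters entering the finite-population sign-test bounds.

    c_F, C_F bound every individual's offspring mean from below and above
    (1 < c_F < C_F); kappa in (1/c_F, 1) is the population-size floor
    fraction; p0, p1 are the frequency floors of the genotype pair; b_j,
    delta_j the selection differential; t_c the checking time.
    """

    c_F: float
    C_F: float
    kappa: float
    n_popmax: int
    p_mut: float
    p0: float
    p1: float
    b_j: float = 1.0
    delta_j: float = 1.0
    t_c: int = 1

    def __post_init__(self):
        if not 1 < self.c_F < self.C_F:
            raise ValueError("need 1 < c_F < C_F")
        if not (1 / self.c_F) < self.kappa < 1:
            raise ValueError("kappa must lie in (1/c_F, 1)")
        if self.n_popmax < 1:
            raise ValueError("n_popmax must be positive")
        if not 0 <= self.p_mut <= 1:
            raise ValueError("p_mut must lie in [0, 1]")
        for name in ("p0", "p1"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.t_c < 1:
            raise ValueError("t_c must be a positive integer")


# ---------------------------------------------------------------------------
# elementary rate functions


def chernoff_d(delta: float) -> float:
    """Poisson-Chernoff rate d(delta) = (1+delta) ln(1+delta) - delta.

    Defined for delta >= -1; d(-1) = 1 by the x ln x -> 0 limit.  Vanishes
    only at delta = 0.
    """
    delta = float(delta)
    if delta < -1:
        raise ValueError("delta must be >= -1")
    if delta == -1:
        return 1.0
    return (1 + delta) * np.log1p(delta) - delta


def poisson_sum_tails(mu_bar: float, n: int, delta: float) -> tuple[float, float]:
    """(upper, lower) tail bounds for a sum of n Poisson variables of mean mu_bar.

    Pr{X > (1+delta) mu n} <= exp(-mu d(delta) n) and
    Pr{X < (1-delta) mu n} <= exp(-mu d(-delta) n).
    """
    if not (mu_bar > 0 and n >= 1 and delta > 0):
        raise ValueError("need mu_bar > 0, n >= 1, delta > 0")
    upper = float(np.exp(-mu_bar * chernoff_d(delta) * n))
    lower = float(np.exp(-mu_bar * chernoff_d(-delta) * n))
    return upper, lower


def bernoulli_half_g(p: float) -> float:
    """Rate g(p) = -p ln(2)/2 - ln(1 - p/2) of the Bernoulli lower-half bound."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return -p * np.log(2) / 2 - np.log(1 - p / 2)


def bernoulli_half_bound(p: float, n: int) -> float:
    """Bound exp(-g(p) n) on Pr{2X < p n} for a sum X of n Bernoulli(p)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.exp(-bernoulli_half_g(p) * n))


def kl_div(x: float, y: float) -> float:
    """Kullback-Leibler divergence D(x||y) between Bernoulli(x) and Bernoulli(y)."""
    if not 0 <= x <= 1:
        raise ValueError("x must lie in [0, 1]")
    if (y <= 0 and x > 0) or (y >= 1 and x < 1):
        raise ValueError("divergence infinite: y on the boundary with x interior")
    terms = 0.0
    if x > 0:
        terms += x * np.log(x / y)
    if x < 1:
        terms += (1 - x) * np.log((1 - x) / (1 - y))
    return float(terms)


def hoeffding_bound(a: float, n: int) -> float:
    """Hoeffding bound min(1, 2 exp(-2 a^2 / n)) on Pr{|X - EX| > a}.

    X is a sum of n independent [0, 1]-valued variables.
    """
    if not (a > 0 and n >= 1):
        raise ValueError("need a > 0 and n >= 1")
    return float(min(1.0, 2 * np.exp(-2 * a * a / n)))


# ---------------------------------------------------------------------------
# mutation-rate exponents (three printed variants, kept separate on purpose)


def u_rate(p: float) -> float:
    """U(p) = 2 ln(2) p + (1-p) ln((1-2p)/(1-p)); ~ (2 ln 2 - 1) p for small p."""
    if not 0 <= p < 0.5:
        raise ValueError("p must lie in [0, 1/2)")
    if p == 0:
        return 0.0
    return float(2 * np.log(2) * p + (1 - p) * np.log((1 - 2 * p) / (1 - p)))


def mutation_rate_exponents(p: float) -> dict[str, float]:
    """The three per-individual exponents used for the mutant-count tail.

    The mutant-count bound is stated through D(2p||p), through g(p), and
    through U(p) in different places; the three expressions are close but not
    identical, so they are evaluated independently here and never silently
    reconciled.
    """
    return {
        "kl": kl_div(min(2 * p, 1.0), p) if p > 0 else 0.0,
        "g": bernoulli_half_g(p),
        "u": u_rate(p),
    }


# ---------------------------------------------------------------------------
# sign-test probability machinery


def epsilon0(
    b_j: float,
    delta_j: float,
    t_c: float,
    p_mut: float | None = None,
    C_F: float | None = None,
) -> Flagged:
    """Replicator-accuracy tolerance eps_0 = tanh(b_j delta_j t_c / 4).

    Equals (1 - e^{-x/2}) / (1 + e^{-x/2}) with x = b_j delta_j t_c.  The
    flag reports the regime condition eps_0 > 4 p_mut C_F when p_mut and C_F
    are supplied (True otherwise).
    """
    if b_j * delta_j * t_c < 0:
        raise ValueError("b_j * delta_j * t_c must be nonnegative")
    x = b_j * delta_j * t_c
    value = float(np.tanh(x / 4))
    in_regime = True
    if p_mut is not None and C_F is not None:
        in_regime = value > 4 * p_mut * C_F
    return Flagged(value, in_regime)


def epsilon_tilde(params: BoundParams) -> float:
    """Massacre-thinning margin eps~ = 1 - 1/(kappa c_F); positive by assumption."""
    return 1 - 1 / (params.kappa * params.c_F)


def rho(p: float, params: BoundParams) -> float:
    """Leading-order false-persistence probability as p_mut -> 0, N_popmax -> oo.

    rho(p) = exp(-(ln 2 - 1/2) p_mut c_F p kappa N_popmax); the q_4 term of
    the full sum dominates in that limit.
    """
    exponent = (
        -(np.log(2) - 0.5)
        * params.p_mut
        * params.c_F
        * p
        * params.kappa
        * params.n_popmax
    )
    return float(np.exp(exponent))


@dataclass
class SignTestBound:
    """Lower bound on the success probability of the co-persistence sign test."""

    pr_v: float
    base: float  # 1 - rho(p0) - rho(p1), possibly negative (then out of regime)
    rejection_threshold: float  # p1 above this refutes j in I_-
    out_of_regime: bool


def sign_test_probability(params: BoundParams) -> SignTestBound:
    """Success-probability bound (1 - rho(p0) - rho(p1))^t_c and the p1 threshold.

    When the base is negative the bound is vacuous: pr_v is clamped to 0 and
    flagged out-of-regime.  The rejection threshold
    p0^{-1} exp(-0.5 |b_j| delta_j t_c) is the largest p1 compatible with the
    disfavoured variant persisting.
    """
    base = 1 - rho(params.p0, params) - rho(params.p1, params)
    out = base <= 0
    pr_v = 0.0 if out else float(base**params.t_c)
    threshold = float(
        np.exp(-0.5 * abs(params.b_j) * params.delta_j * params.t_c) / params.p0
    )
    return SignTestBound(pr_v, float(base), threshold, out)


def q_functions(p: float, params: BoundParams) -> dict[str, float]:
    """The six exponential terms of the full false-persistence probability.

    Returns q1..q5, q_tilde and their sum rho_full; N(s, t) floors are
    kappa p N_popmax as in the uniform population-size estimates.  q4
    carries the mutation-rate exponent U(p_mut) and dominates as
    p_mut -> 0, N_popmax -> oo.
    """
    eps0 = epsilon0(params.b_j, params.delta_j, params.t_c).value
    eps_t = epsilon_tilde(params)
    if eps_t <= 0:
        raise ValueError("kappa * c_F must exceed 1")
    cF, CF, kappa, n = params.c_F, params.C_F, params.kappa, params.n_popmax
    q1 = np.exp(-(2 * np.log(2) - 1) * cF * kappa * n) + np.exp(-cF * kappa * n)
    q2 = 2 * np.exp(
        -(1.5 * np.log(1.5) - 0.5) * cF * p * kappa * n
    ) + np.exp(-0.5 * (1 - np.log(2)) * cF * p * kappa * n)
    q3 = 2 * np.exp(-(eps0**2) / (16 * CF**2) * kappa * cF * p * n)
    q4 = np.exp(-0.5 * u_rate(params.p_mut) * cF * p * kappa * n)
    q5 = np.exp(-(2 * np.log(2) - 1) * cF * kappa * p * n) + np.exp(
        -cF * p * kappa * n
    )
    # Hoeffding term of the massacre estimate with eps_2 = 1 - kappa and
    # progeny pool at most 2 (1 + eps~) C_F N_popmax
    q_tilde = (
        np.exp(-chernoff_d(eps_t) * kappa * n)
        + np.exp(-chernoff_d(-eps_t) * kappa * n)
        + 2 * np.exp(-((1 - kappa) ** 2) * n / ((1 + eps_t) * CF))
    )
    out = {
        "q1": float(q1),
        "q2": float(q2),
        "q3": float(q3),
        "q4": float(q4),
        "q5": float(q5),
        "q_tilde": float(q_tilde),
    }
    out["rho_full"] = float(sum(out.values()))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo validation


def _freq_and_se(hits: np.ndarray) -> tuple[float, float]:
    freq = float(np.mean(hits))
    se = float(np.sqrt(freq * (1 - freq) / hits.size))
    return freq, se


def mc_poisson_sum_tails(
    mu_bar: float, n: int, delta: float, n_draws: int = 100_000, rng=None
) -> dict[str, float]:
    """Empirical upper/lower tail frequencies of a sum of n Poisson(mu_bar).

    The sum is itself Poisson(n mu_bar), so each draw is a single Poisson
    variate.  Returns empirical frequencies, their standard errors and the
    corresponding bounds.
    """
    rng = np.random.default_rng(rng)
    x = rng.poisson(mu_bar * n, size=n_draws)
    up_f, up_se = _freq_and_se(x > (1 + delta) * mu_bar * n)
    lo_f, lo_se = _freq_and_se(x < (1 - delta) * mu_bar * n)
    up_b, lo_b = poisson_sum_tails(mu_bar, n, delta)
    return {
        "upper_freq": up_f,
        "upper_se": up_se,
        "upper_bound": up_b,
        "lower_freq": lo_f,
        "lower_se": lo_se,
        "lower_bound": lo_b,
    }


def mc_bernoulli_half(
    p: float, n: int, n_draws: int = 100_000, rng=None
) -> dict[str, float]:
    """Empirical frequency of {2X < p n} for X ~ Binomial(n, p), plus bound."""
    rng = np.random.default_rng(rng)
    x = rng.binomial(n, p, size=n_draws)
    freq, se = _freq_and_se(2 * x < p * n)
    return {"freq": freq, "se": se, "bound": bernoulli_half_bound(p, n)}


def mc_hoeffding_tail(
    p: float, n: int, a: float, n_draws: int = 100_000, rng=None
) -> dict[str, float]:
    """Empirical frequency of {|X - np| > a} for X ~ Binomial(n, p), plus bound."""
    rng = np.random.default_rng(rng)
    x = rng.binomial(n, p, size=n_draws)
    freq, se = _freq_and_se(np.abs(x - n * p) > a)
    return {"freq": freq, "se": se, "bound": hoeffding_bound(a, n)}


def bounds_report(
    poisson_grid=((0.5, 10, 0.2), (0.5, 100, 0.5), (1.0, 10, 0.5),
                  (1.0, 100, 1.0), (2.0, 10, 1.0), (2.0, 100, 0.2)),
    bernoulli_grid=((0.1, 50), (0.3, 100), (0.5, 200)),
    hoeffding_grid=((0.3, 50, 10.0), (0.5, 100, 15.0), (0.7, 200, 25.0)),
    n_draws: int = 100_000,
    rng=None,
    slack_se: float = 3.0,
) -> pd.DataFrame:
    """Tabulate every bound against its empirical tail on a parameter grid.

    A row passes when the bound is at least the empirical frequency minus
    ``slack_se`` Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for mu, n, delta in poisson_grid:
        r = mc_poisson_sum_tails(mu, n, delta, n_draws, rng)
        for side in ("upper", "lower"):
            rows.append(
                {
                    "family": f"poisson_{side}",
                    "params": f"mu={mu},n={n},delta={delta}",
                    "bound": r[f"{side}_bound"],
                    "empirical": r[f"{side}_freq"],
                    "mc_se": r[f"{side}_se"],
                }
            )
    for p, n in bernoulli_grid:
        r = mc_bernoulli_half(p, n, n_draws, rng)
        rows.append(
            {
                "family": "bernoulli_half",
                "params": f"p={p},n={n}",
                "bound": r["bound"],
                "empirical": r["freq"],
                "mc_se": r["se"],
            }
        )
    for p, n, a in hoeffding_grid:
        r = mc_hoeffding_tail(p, n, a, n_draws, rng)
        rows.append(
            {
                "family": "hoeffding",
                "params": f"p={p},n={n},a={a}",
                "bound": r["bound"],
                "empirical": r["freq"],
                "mc_se": r["se"],
            }
        )
    df = pd.DataFrame.from_records(rows)
    df["passes"] = df["bound"] >= df["empirical"] - slack_se * df["mc_se"]
    return df
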