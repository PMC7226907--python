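"""Closed-form scaling theory of CMP on uncorrelated power-law networks.

All predictions use the continuous-approximation degree distribution
P(k) = (gamma-1) kmin^(gamma-1) k^-gamma, k >= kmin.  The central degree
scales are

* ``kc(ka) = (ka/kmin)^(gamma-2)`` — the inverse of the active-neighbour
  probability Pa, separating nodes likely to have many active neighbours
  (k >> kc) from likely-isolated ones;
* ``k0_star`` — where kc(k) = k, the end of the regime in which essentially
  all active nodes sit in the giant cluster;
* ``k1_star`` — where the non-isolated contribution to the giant cluster is
  overtaken by isolated nodes of range >= 2 (equating the two large-ka
  asymptotics);
* ``k2_star`` — where the extended-DOP giant-cluster size S1 is overtaken by
  the distant-hub mechanism size S2, solved numerically from S1(k) = S2(k).

The incomplete gamma function with negative first argument is evaluated by
the downward recurrence Gamma(a-1, x) = (Gamma(a, x) - x^(a-1) e^-x)/(a-1)
starting from a positive (or the exponential-integral) base, with an
adaptive-quadrature fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize, special

from .netgen import kappa_theory

__all__ = [
    "TheoryParams",
    "CrossoverScales",
    "ThresholdEstimate",
    "active_fraction",
    "prob_active_neighbor",
    "kc",
    "k0_star",
    "mean_active_neighbors",
    "upper_incomplete_gamma",
    "f_nonisolated",
    "f_isolated_r2",
    "f_nonisolated_asymptotic",
    "f_isolated_r2_asymptotic",
    "S1",
    "k1_star",
    "k1_star_numeric",
    "d_of_k",
    "omega",
    "S2",
    "k2_star",
    "effective_ka_threshold",
]


@dataclass(frozen=True)
class TheoryParams:
    """Parameters entering every closed-form prediction.

    gamma : degree exponent (> 2)
    kmin : minimum degree
    kappa : branching factor <k^2>/<k> - 1; None uses the
        continuous-approximation value kmin (gamma-2)/(gamma-3) - 1
        (requires gamma > 3), a measured value may be passed instead
    a : SIS activation constant relating ka and lambda (1 or 4; not
        theoretically determined, so it is always explicit downstream)
    """

    gamma: float
    kmin: float
    kappa: float | None = None
    a: float = 1.0

    def __post_init__(self):
        if not self.gamma > 2:
            raise ValueError("gamma must be > 2")
        if self.kmin < 1:
            raise ValueError("kmin must be >= 1")

    def kappa_value(self) -> float:
        k = self.kappa if self.kappa is not None else kappa_theory(self.gamma, self.kmin)
        if k <= 1:
            raise ValueError("kappa must be > 1 wherever ln(kappa) enters")
        return k


@dataclass(frozen=True)
class CrossoverScales:
    """Degree scales of the successive scaling regimes, plus N2* = k2*^(gamma-1)."""

    k0_star: float
    k1_star: float
    k2_star: float
    N2_star: float


class ThresholdEstimate(NamedTuple):
    value: float
    asymptotic: bool  # True when the result is a prefactor-free scaling law


def _check_ka(ka, params: TheoryParams) -> None:
    if np.any(np.asarray(ka) < params.kmin):
        raise ValueError("ka must be >= kmin")


def active_fraction(ka, params: TheoryParams):
    """Fraction of active nodes Na/N = (ka/kmin)^(1-gamma)."""
    _check_ka(ka, params)
    return (np.asarray(ka, dtype=float) / params.kmin) ** (1.0 - params.gamma)


def prob_active_neighbor(ka, params: TheoryParams):
    """Probability Pa = (ka/kmin)^(2-gamma) that a given neighbour is active."""
    _check_ka(ka, params)
    return (np.asarray(ka, dtype=float) / params.kmin) ** (2.0 - params.gamma)


def kc(ka, params: TheoryParams):
    """Isolation degree scale kc = 1/Pa = (ka/kmin)^(gamma-2)."""
    return (np.asarray(ka, dtype=float) / params.kmin) ** (params.gamma - 2.0)


def k0_star(params: TheoryParams) -> float:
    """Solution of kc(k) = k: k0* = kmin^((gamma-2)/(gamma-3)); gamma > 3 only."""
    if params.gamma <= 3:
        raise ValueError("k0* is defined only for gamma > 3")
    g = params.gamma
    return float(params.kmin ** ((g - 2.0) / (g - 3.0)))


def mean_active_neighbors(ka, params: TheoryParams):
    """Mean number of active neighbours of an active node,
    (gamma-1)/(gamma-2) * ka * Pa ~ ka^(3-gamma)."""
    g = params.gamma
    return (g - 1.0) / (g - 2.0) * np.asarray(ka, dtype=float) * prob_active_neighbor(
        ka, params
    )


# ------------------------------------------------------------ incomplete gamma

def _upper_gamma_quad(a: float, x: float) -> float:
    val, _ = integrate.quad(
        lambda t: t ** (a - 1.0) * np.exp(-t), x, np.inf, limit=200
    )
    return val


def upper_incomplete_gamma(a: float, x: float) -> float:
    """Upper incomplete gamma Gamma(a, x) for real a (negative allowed), x > 0."""
    if x <= 0:
        raise ValueError("x must be > 0")
    if a > 0:
        return float(special.gammaincc(a, x) * special.gamma(a))
    n = int(np.ceil(-a))
    a0 = a + n
    try:
        if abs(a0) < 1e-12:
            g = float(special.exp1(x))
            a_cur = 0.0
        else:
            g = float(special.gammaincc(a0, x) * special.gamma(a0))
            a_cur = a0
        emx = np.exp(-x)
        for _ in range(n):
            a_cur -= 1.0
            g = (g - x**a_cur * emx) / a_cur
        if not np.isfinite(g):
            raise FloatingPointError("recurrence produced non-finite value")
        return g
    except FloatingPointError:
        warnings.warn("incomplete-gamma recurrence failed; using quadrature")
        return _upper_gamma_quad(a, x)


# ------------------------------------------------- extended-DOP mechanism (S1)

def f_nonisolated(ka: float, params: TheoryParams) -> float:
    """Fraction of non-isolated active nodes N_NI/N.

    Closed form (gamma-1) kmin^(gamma-1) [ka^(1-gamma)/(gamma-1)
    - kc^(1-gamma) Gamma(1-gamma, ka/kc)], equal to the integral of
    P(k) (1 - e^(-k/kc)) over k >= ka.
    """
    _check_ka(ka, params)
    g, kmin = params.gamma, params.kmin
    kc_ = float(kc(ka, params))
    val = (g - 1.0) * kmin ** (g - 1.0) * (
        ka ** (1.0 - g) / (g - 1.0)
        - kc_ ** (1.0 - g) * upper_incomplete_gamma(1.0 - g, ka / kc_)
    )
    return max(val, 0.0)


def f_isolated_r2(ka: float, params: TheoryParams) -> float:
    """Fraction of isolated active nodes with range >= 2 (degree >= 2 ka),
    (gamma-1) kmin^(gamma-1) kc^(1-gamma) Gamma(1-gamma, 2 ka/kc)."""
    _check_ka(ka, params)
    g, kmin = params.gamma, params.kmin
    kc_ = float(kc(ka, params))
    val = (
        (g - 1.0)
        * kmin ** (g - 1.0)
        * kc_ ** (1.0 - g)
        * upper_incomplete_gamma(1.0 - g, 2.0 * ka / kc_)
    )
    return max(val, 0.0)


def f_nonisolated_asymptotic(ka, params: TheoryParams):
    """Large-ka form (ka/kmin)^(1-gamma) (gamma-1)/(gamma-2) (ka/kc) ~ ka^(2(2-gamma))."""
    g = params.gamma
    ka = np.asarray(ka, dtype=float)
    return (ka / params.kmin) ** (1.0 - g) * (g - 1.0) / (g - 2.0) * ka / kc(ka, params)


def f_isolated_r2_asymptotic(ka, params: TheoryParams):
    """Large-ka form (2 ka/kmin)^(1-gamma) [1 - (gamma-1)/(gamma-2) 2 ka/kc]."""
    g = params.gamma
    ka = np.asarray(ka, dtype=float)
    lead = (2.0 * ka / params.kmin) ** (1.0 - g)
    return lead * (1.0 - (g - 1.0) / (g - 2.0) * 2.0 * ka / kc(ka, params))


def S1(ka: float, params: TheoryParams) -> float:
    """Giant-cluster fraction from the extended-DOP mechanism,
    S1 = N_NI/N + N_{r>=2}/N; asymptotic log-slope 2(2-gamma)."""
    if params.gamma <= 3:
        raise ValueError("S1 applies to gamma > 3")
    return f_nonisolated(ka, params) + f_isolated_r2(ka, params)


def k1_star(params: TheoryParams) -> float:
    """Degree scale where the two contributions to S1 cross.

    Obtained by equating the large-ka asymptotics of N_NI/N and N_{r>=2}/N:
    k1* = [(gamma-2)/(gamma-1) * 2^(1-gamma)/(1+2^(2-gamma))
           * kmin^(2-gamma)]^(1/(3-gamma)).
    """
    g = params.gamma
    if g <= 3:
        raise ValueError("k1* is defined only for gamma > 3")
    inner = (
        (g - 2.0)
        / (g - 1.0)
        * 2.0 ** (1.0 - g)
        / (1.0 + 2.0 ** (2.0 - g))
        * params.kmin ** (2.0 - g)
    )
    return float(inner ** (1.0 / (3.0 - g)))


def k1_star_numeric(params: TheoryParams) -> float:
    """k1* by root-finding on the two asymptotic expressions (independent of
    the closed form)."""
    g = params.gamma
    if g <= 3:
        raise ValueError("k1* is defined only for gamma > 3")

    def diff(logk):
        k = np.exp(logk)
        return float(
            f_nonisolated_asymptotic(k, params) - f_isolated_r2_asymptotic(k, params)
        )

    lo, hi = np.log(params.kmin), np.log(1e12)
    if diff(lo) * diff(hi) > 0:
        raise ValueError("no crossing of the two asymptotics in the bracket")
    return float(np.exp(optimize.brentq(diff, lo, hi, xtol=1e-12, rtol=1e-12)))


# ------------------------------------------------ distant-hub mechanism (S2)

def d_of_k(k, params: TheoryParams):
    """Mean distance from a degree-k node to its closest peer of degree >= k,
    d(k) = 1 + (gamma-3)/ln(kappa) * ln(k/kmin) (large-network limit)."""
    if np.any(np.asarray(k) < params.kmin):
        raise ValueError("k must be >= kmin")
    kap = params.kappa_value()
    return 1.0 + (params.gamma - 3.0) / np.log(kap) * np.log(
        np.asarray(k, dtype=float) / params.kmin
    )


def omega(
    ka: float,
    params: TheoryParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> float:
    """Fixed point omega >= 1 of omega = 1 + (gamma-3)/ln(kappa) ln(omega ka/kmin).

    Solved by damped iteration from omega = 1; the map is a slowly varying
    logarithm, so heavy damping converges reliably.  kx = omega * ka is the
    degree above which a node's range exceeds the distance to its nearest
    peer, triggering the distant-hub merging cascade.
    """
    _check_ka(ka, params)
    if params.gamma <= 3:
        raise ValueError("omega is defined only for gamma > 3")
    c = (params.gamma - 3.0) / np.log(params.kappa_value())
    w = 1.0
    for _ in range(max_iter):
        w_new = (1.0 - damping) * w + damping * (
            1.0 + c * np.log(w * ka / params.kmin)
        )
        if abs(w_new - w) < tol:
            return float(w_new)
        w = w_new
    raise RuntimeError(f"omega fixed point did not converge; last iterate {w}")


def S2(ka: float, params: TheoryParams) -> float:
    """Giant-cluster fraction from the distant-hub mechanism,
    S2 = omega^(1-gamma) (ka/kmin)^(1-gamma) (power law times log correction)."""
    w = omega(ka, params)
    return float(w ** (1.0 - params.gamma) * (ka / params.kmin) ** (1.0 - params.gamma))


def _log10_f_nonisolated_mp(ka: float, params: TheoryParams) -> float:
    """log10 of the full N_NI/N closed form evaluated at 50-digit precision.

    At the huge degrees where the crossover solve operates the bracket in the
    N_NI/N closed form cancels catastrophically in double precision, so it is
    evaluated with mpmath.
    """
    import mpmath as mp

    with mp.workdps(50):
        g = mp.mpf(params.gamma)
        kmin = mp.mpf(params.kmin)
        k = mp.mpf(ka)
        kc_ = (k / kmin) ** (g - 2)
        x = k / kc_
        gam = mp.gammainc(1 - g, x, mp.inf)
        ni = (g - 1) * kmin ** (g - 1) * (k ** (1 - g) / (g - 1) - kc_ ** (1 - g) * gam)
        return float(mp.log10(ni))


def k2_star(params: TheoryParams, log10_hi: float = 60.0) -> CrossoverScales:
    """Crossover where the distant-hub mechanism overtakes extended DOP.

    Solves S1(k2*) = S2(k2*) for k2* > k1*, where S1 here is its observed
    preasymptotic branch N_NI/N (the full closed form, not its power-law
    asymptote).  The isolated-r>=2 contribution must be excluded: beyond k1*
    it shares the ka^(1-gamma) leading power of S2 with a larger prefactor,
    so including it the two curves would never cross — and the cluster
    accounting shows that contribution is suppressed anyway, with N_NI
    dominating inside the giant cluster at all accessible ka.  Reports
    N2* = k2*^(gamma-1), the minimum network size whose natural degree cutoff
    reaches k2*; k0* and k1* are returned for context.
    """
    if params.gamma <= 3:
        raise ValueError("k2* is defined only for gamma > 3")
    k1 = k1_star(params)

    def diff(log10k: float) -> float:
        k = 10.0**log10k
        return _log10_f_nonisolated_mp(k, params) - np.log10(S2(k, params))

    # march upward in decades from just above k0* (where the Eq.-17 regime
    # sets in) until the sign flips; near gamma = 3 the root can sit slightly
    # below k1*, so k1* is not a safe lower bracket
    lo = np.log10(max(2.0 * k0_star(params), 4.0 * params.kmin))
    hi = lo + 1.0
    flo = diff(lo)
    while hi <= log10_hi:
        fhi = diff(hi)
        if flo * fhi <= 0:
            break
        lo, flo = hi, fhi
        hi += 1.0
    else:
        raise ValueError("no S1 = S2 crossing found up to 10^%g" % log10_hi)
    root = optimize.brentq(diff, lo, hi, xtol=1e-9)
    k2 = float(10.0**root)
    return CrossoverScales(
        k0_star=k0_star(params),
        k1_star=k1,
        k2_star=k2,
        N2_star=float(k2 ** (params.gamma - 1.0)),
    )


# ---------------------------------------------------- finite-size thresholds

def effective_ka_threshold(
    kmax: float,
    params: TheoryParams,
    regime: str = "auto",
) -> ThresholdEstimate:
    """Finite-size effective activation threshold ka_c for a network whose
    degree sequence is cut off at kmax.

    gamma < 3 : ka_c = kmax (no active nodes above it).
    gamma > 3, kmax < k2* : ka_c = kmin * kmax^(1/(gamma-2)) (set by
        kc(ka_c) = kmax, the end of the extended-DOP regime).
    gamma > 3, kmax > k2* : ka_c ~ (ln kappa)/(gamma-3) * kmax/ln(kmax)
        (set by kx = kmax; asymptotic, prefactor-free, flagged as such).

    ``regime`` may force ``"preasymptotic"`` or ``"asymptotic"`` to skip the
    k2* comparison.  gamma within 0.05 of 3 is rejected as ill-defined.
    """
    if kmax < params.kmin:
        raise ValueError("kmax must be >= kmin")
    g = params.gamma
    if abs(g - 3.0) < 0.05:
        raise ValueError("regime ill-defined for gamma ~ 3")
    if g < 3:
        return ThresholdEstimate(float(kmax), False)
    if regime == "auto":
        regime = "preasymptotic" if kmax < k2_star(params).k2_star else "asymptotic"
    if regime == "preasymptotic":
        return ThresholdEstimate(
            float(params.kmin * kmax ** (1.0 / (g - 2.0))), False
        )
    if regime == "asymptotic":
        kap = params.kappa_value()
        return ThresholdEstimate(
            float(np.log(kap) / (g - 3.0) * kmax / np.log(kmax)), True
        )
    raise ValueError("regime must be 'auto', 'preasymptotic' or 'asymptotic'")
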