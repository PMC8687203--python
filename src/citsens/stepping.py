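"""Adaptive step selection for the implicit leap: partial-equilibrium
detection, critical-reaction partitioning and the two candidate step sizes.

A reversible pair is in partial equilibrium when its forward and backward
propensities nearly balance,

    |a+ - a-| <= delta * min{a+, a-},

and is then exempted from the leap-size constraint.  A reaction is critical
when some reactant is within n_c firings of exhaustion; critical reactions
fire one at a time with exact (exponential) waiting times while all other
channels are leaped over implicitly.  The non-critical candidate step tau1
bounds the expected change and the variance of each reactant population by
max{eps * x_i / g_i, 1}, where g_i accounts for the highest order at which
species i reacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork


@dataclass
class LeapControls:
    """Tunable controls of the adaptive implicit leap.

    epsilon
        Leap tolerance (relative change of reactant populations allowed per
        step), in (0, 1).
    delta
        Partial-equilibrium threshold for reversible pairs.
    n_c
        Critical-reaction threshold in firings; admissible range is roughly
        2..20 (larger values trade efficiency for protection against
        negative populations).
    newton_tol
        Newton convergence tolerance TOL (infinity norm of the update).
    """

    epsilon: float = 0.05
    delta: float = 0.05
    n_c: int = 10
    newton_tol: float = 0.01
    max_newton_iter: int = 50
    max_step_retries: int = 12

    def __post_init__(self):
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0,1)")
        if self.delta <= 0 or self.newton_tol <= 0:
            raise ValueError("delta and newton_tol must be > 0")
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")


@dataclass
class ReactionPartition:
    """Boolean masks over the M reaction channels for one leap step.

    ``crit``: critical channels (advanced by exact single firings);
    ``ncr``: non-critical channels (leaped over); ``ne``: channels not in a
    partial-equilibrium pair; ``necr`` = ncr & ne drives the tau1 bound;
    ``L``: per-channel exhaustion counts (min over both paths).
    """

    crit: np.ndarray
    ncr: np.ndarray
    ne: np.ndarray
    L: np.ndarray
    necr: np.ndarray = field(init=False)

    def __post_init__(self):
        self.necr = self.ncr & self.ne

    @property
    def J_cr(self) -> np.ndarray:
        return np.flatnonzero(self.crit)

    @property
    def J_ncr(self) -> np.ndarray:
        return np.flatnonzero(self.ncr)


def partial_equilibrium_flags(
    net: ReactionNetwork, a: np.ndarray, delta: float
) -> np.ndarray:
    """Per-reversible-pair equilibrium flags from one propensity vector."""
    flags = np.empty(len(net.reversible_pairs), dtype=bool)
    for p, (jf, jb) in enumerate(net.reversible_pairs):
        ap, am = a[jf], a[jb]
        flags[p] = abs(ap - am) <= delta * min(ap, am)
    return flags


def equilibrium_reaction_mask(
    net: ReactionNetwork, pair_flags: np.ndarray
) -> np.ndarray:
    """Expand pair flags to a per-reaction mask (True = in equilibrium)."""
    mask = np.zeros(net.M, dtype=bool)
    for p, (jf, jb) in enumerate(net.reversible_pairs):
        if pair_flags[p]:
            mask[jf] = mask[jb] = True
    return mask


def exhaustion_counts(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """L_j = min over consumed species of floor(x_i / |nu_ij|); +inf when a
    channel consumes nothing (it can never drive a population negative)."""
    L = np.full(net.M, np.inf)
    for j, consumed in enumerate(net.consumed_species()):
        best = math.inf
        for i, d in consumed:
            v = x[i] // d
            if v < best:
                best = v
        L[j] = best
    return L


def classify_critical(
    net: ReactionNetwork,
    x_c: np.ndarray,
    x_ch: np.ndarray,
    a_c: np.ndarray,
    a_ch: np.ndarray,
    n_c: int,
    eq_mask: np.ndarray | None = None,
) -> ReactionPartition:
    """Partition the active channels of a coupled pair.

    A channel is considered when its propensity is positive on either path;
    its exhaustion count is the minimum over the two paths, so a reaction
    critical on either path is critical for both.  Channels belonging to a
    flagged partial-equilibrium pair are never critical (they are excluded
    from the not-in-equilibrium set before criticality is applied).
    """
    if eq_mask is None:
        eq_mask = np.zeros(net.M, dtype=bool)
    active = (a_c > 0) | (a_ch > 0)
    L = np.minimum(exhaustion_counts(net, x_c), exhaustion_counts(net, x_ch))
    crit = active & ~eq_mask & (L < n_c)
    ncr = active & ~crit
    return ReactionPartition(crit=crit, ncr=ncr, ne=~eq_mask, L=L)


def g_exponent(psi: int, mult: int, x_i: float) -> float:
    """Leap exponent g_i from the highest-order rules.

    psi is the highest order at which the species reacts within the subset,
    mult the largest multiplicity with which it appears in a reaction of
    that order.  Degenerate populations (divisor <= 0) fall back to
    g_i = psi; the leap bound max{eps*x/g, 1} is clamped at 1 there anyway.
    """
    if psi <= 1:
        return 1.0
    if psi == 2:
        if mult >= 2:
            if x_i - 1 <= 0:
                return 2.0
            return 2.0 + 1.0 / (x_i - 1.0)
        return 2.0
    # psi == 3
    if mult >= 3:
        if x_i - 2 <= 0:
            return 3.0
        return 3.0 + 1.0 / (x_i - 1.0) + 2.0 / (x_i - 2.0)
    if mult == 2:
        if x_i - 1 <= 0:
            return 3.0
        return 1.5 * (2.0 + 1.0 / (x_i - 1.0))
    return 3.0


def _necr_structure(net: ReactionNetwork, necr: np.ndarray):
    """Cached per-mask structure for tau1: stoichiometry slices and the
    species order table (masks recur step after step along a path)."""
    cache = getattr(net, "_tau_cache", None)
    if cache is None:
        cache = net._tau_cache = {}
    key = necr.tobytes()
    hit = cache.get(key)
    if hit is None:
        nu_sub = net.nu[:, necr].astype(float)
        hit = (nu_sub, nu_sub ** 2,
               list(net.species_reaction_orders(necr).items()))
        cache[key] = hit
    return hit


def tau_noncritical(
    net: ReactionNetwork,
    x: np.ndarray,
    a: np.ndarray,
    partition: ReactionPartition,
    eps: float,
) -> float:
    """Candidate step tau1 for one path over the non-critical,
    not-in-equilibrium channels; +inf when no such channel constrains."""
    necr = partition.necr
    if not necr.any():
        return math.inf
    nu_sub, nu_sub_sq, orders = _necr_structure(net, necr)
    a_sub = a[necr]
    mu = nu_sub @ a_sub
    sig2 = nu_sub_sq @ a_sub
    tau = math.inf
    for i, (psi, mult) in orders:
        g = g_exponent(psi, mult, float(x[i]))
        bound = max(eps * float(x[i]) / g, 1.0)
        if mu[i] != 0.0:
            tau = min(tau, bound / abs(mu[i]))
        if sig2[i] != 0.0:
            tau = min(tau, bound * bound / sig2[i])
    return tau


def tau_critical(a: np.ndarray, partition: ReactionPartition, xi1: float) -> float:
    """Exponential waiting time to the next critical firing on one path."""
    a0cr = float(a[partition.crit].sum())
    if a0cr <= 0.0:
        return math.inf
    return math.log(1.0 / xi1) / a0cr


def select_critical_reaction(
    partition: ReactionPartition, a: np.ndarray, xi2: float
) -> int:
    """Smallest critical index whose cumulative propensity exceeds
    xi2 * a0^cr (cumulating in ascending reaction-index order)."""
    idx = partition.J_cr
    ai = a[idx]
    a0 = ai.sum()
    if a0 <= 0.0:
        raise ValueError("no critical reaction has positive propensity")
    pos = int(np.searchsorted(np.cumsum(ai), xi2 * a0, side="right"))
    pos = min(pos, len(idx) - 1)  # guard xi2 == 1 boundary
    return int(idx[pos])
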