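"""Exact stochastic simulation: direct-method SSA and the coupled
next-reaction machinery that drives the exact finite-difference baseline.

The coupled simulator implements the random-time-change coupling: each
reaction channel j is split into a shared channel with rate
m_j = min(a_j^c(X^c), a_j^{c+h}(X^{c+h})) that fires in both paths, and two
residual channels with rates a_j^c - m_j and a_j^{c+h} - m_j that fire in
one path each.  The 3M channels are advanced with the modified
next-reaction method over internal times of unit-rate Poisson processes,
with all rates refreshed after every firing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork


class PropensityOverflowError(RuntimeError):
    """A propensity evaluated to a non-finite value along a path."""


@dataclass(frozen=True)
class OutputGrid:
    """Uniform recording grid on [t_start, t_end] with n_points samples."""

    t_start: float
    t_end: float
    n_points: int

    def __post_init__(self):
        if not (self.t_end > self.t_start and self.n_points >= 1):
            raise ValueError("grid requires t_end > t_start and n_points >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


class RngStreams:
    """Reproducible named substreams derived from one master seed.

    ``substream(*key)`` returns an independent PCG64 generator keyed by a
    tuple of integers (e.g. a path index); identical master seed and key
    reproduce the stream bit-for-bit.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def substream(self, *key: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key))
        return np.random.Generator(np.random.PCG64(ss))


def ssa_path(
    net: ReactionNetwork,
    x0: np.ndarray,
    T: float,
    rng: np.random.Generator,
    grid: OutputGrid,
) -> np.ndarray:
    """One exact direct-method trajectory, recorded on ``grid``.

    The next reaction index is the smallest j whose cumulative propensity
    exceeds xi1 * a0; the waiting time is ln(1/xi2)/a0.  When a0 = 0 the
    state is frozen to T.  Recording is piecewise-constant (the jump
    process is left-continuous on the grid).
    """
    x = [int(v) for v in np.asarray(x0)]
    t = 0.0
    times = grid.times
    n = grid.n_points
    out = np.empty((n, net.N), dtype=np.int64)
    gi = 0
    evaluate = net.compiled_propensities()
    nu_sparse = net.nu_sparse
    a = [0.0] * net.M
    M = net.M
    log = math.log
    while t < T:
        evaluate(x, a)
        a0 = 0.0
        for v in a:
            a0 += v
        if not math.isfinite(a0):
            raise PropensityOverflowError(
                f"non-finite propensity at t={t:.6g}, x={x}"
            )
        if a0 <= 0.0:
            break
        xi1 = rng.random()
        xi2 = rng.random()
        t_next = t + log(1.0 / xi2) / a0
        limit = t_next if t_next < T else T
        while gi < n and times[gi] < limit:
            out[gi] = x
            gi += 1
        if t_next > T:
            t = T
            break
        # smallest j with cumulative propensity > xi1 * a0
        target = xi1 * a0
        acc = 0.0
        j = M - 1
        for jj in range(M):
            acc += a[jj]
            if acc > target:
                j = jj
                break
        for i, d in nu_sparse[j]:
            x[i] += d
        t = t_next
    # freeze remaining grid points at the final state
    while gi < n:
        out[gi] = x
        gi += 1
    return out


def coupled_next_reaction_paths(
    net: ReactionNetwork,
    param_index: int,
    h: float,
    x0: np.ndarray,
    T: float,
    rng: np.random.Generator,
    grid: OutputGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact coupled pair (X^c, X^{c+h}) on ``grid``.

    Channel layout per reaction j: 3j shared (rate m_j), 3j+1 nominal
    residual, 3j+2 perturbed residual.  Ties between firing times are
    broken toward the lowest channel index (argmin), which keeps identical
    seeds reproducible.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    net_h = net.with_perturbed_rate(param_index, h)
    xc = [int(v) for v in np.asarray(x0)]
    xh = list(xc)
    M = net.M
    M3 = 3 * M
    # internal clocks T_k and next internal firing times P_k of the
    # unit-rate Poisson processes Y_{j,1..3}
    Tk = [0.0] * M3
    Pk = list(rng.exponential(size=M3))
    t = 0.0
    times = grid.times
    n = grid.n_points
    out_c = np.empty((n, net.N), dtype=np.int64)
    out_h = np.empty((n, net.N), dtype=np.int64)
    gi = 0
    eval_c = net.compiled_propensities()
    eval_h = net_h.compiled_propensities()
    nu_sparse = net.nu_sparse
    ac = [0.0] * M
    ah = [0.0] * M
    rates = [0.0] * M3
    inf = math.inf
    while t < T:
        eval_c(xc, ac)
        eval_h(xh, ah)
        for j in range(M):
            acj = ac[j]
            ahj = ah[j]
            m = acj if acj < ahj else ahj
            k = 3 * j
            rates[k] = m
            rates[k + 1] = acj - m
            rates[k + 2] = ahj - m
        delta = inf
        kmin = -1
        for k in range(M3):
            rk = rates[k]
            if rk > 0.0:
                d = (Pk[k] - Tk[k]) / rk
                if d < delta:
                    delta = d
                    kmin = k
        if not math.isfinite(delta):
            break
        t_next = t + delta
        limit = t_next if t_next < T else T
        while gi < n and times[gi] < limit:
            out_c[gi] = xc
            out_h[gi] = xh
            gi += 1
        if t_next > T:
            t = T
            break
        for k in range(M3):
            Tk[k] += rates[k] * delta
        j, which = divmod(kmin, 3)
        col = nu_sparse[j]
        if which != 2:
            for i, d in col:
                xc[i] += d
        if which != 1:
            for i, d in col:
                xh[i] += d
        Pk[kmin] += rng.exponential()
        t = t_next
    while gi < n:
        out_c[gi] = xc
        out_h[gi] = xh
        gi += 1
    return out_c, out_h
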