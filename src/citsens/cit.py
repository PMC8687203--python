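"""Coupled implicit tau-leaping (CIT) finite-difference sensitivity
estimation, plus the single-path adaptive implicit leap simulator and the
ensemble driver shared by every estimator variant.

The estimator targets the forward finite difference

    S(t) = [E f(X^{c+h}(t)) - E f(X^c(t))] / h

for an observable f and a perturbed stochastic rate constant c -> c + h.
Nominal and perturbed paths are advanced together by implicit tau-leaping
with shared Poisson increments: per non-critical channel j the firing count
splits into a shared part P1_j ~ Poisson(m_j tau) with
m_j = min(a_j^c, a_j^{c+h}) and residual parts P2_j, P3_j driven by the
propensity surpluses of each leg.  The shared part dominates when h is
small, so the two legs stay close and the variance of the per-path
difference Z(t) = (f(X^{c+h}) - f(X^c))/h collapses relative to an
uncoupled estimator.  Critical reactions (near-exhausted reactants) are
advanced by exact single firings layered on top of each leap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork
from .ssa import OutputGrid, RngStreams, ssa_path, coupled_next_reaction_paths
from .stepping import (
    LeapControls,
    ReactionPartition,
    classify_critical,
    equilibrium_reaction_mask,
    partial_equilibrium_flags,
    select_critical_reaction,
    tau_critical,
    tau_noncritical,
)
from .leap import round_state, solve_implicit_state, ImplicitSolveReport

_REL_EPS = 1e-12  # time-comparison slack relative to T


class PathAbortedError(RuntimeError):
    """A sample path exhausted its step-retry budget."""


@dataclass
class CoupledState:
    """Nominal and perturbed states sharing one clock."""

    x_c: np.ndarray
    x_ch: np.ndarray
    t: float
    param_index: int
    h: float


@dataclass
class PoissonIncrements:
    """Shared/residual firing counts of one coupled leap (non-critical
    channels only).  P2_j = 0 wherever the nominal propensity equals m_j,
    P3_j = 0 wherever the perturbed one does."""

    m: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray


@dataclass
class SensitivitySeries:
    """Ensemble finite-difference sensitivity on an output grid."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    R: int
    method: str
    aborted: int = 0
    mean_f_c: np.ndarray | None = None
    mean_f_ch: np.ndarray | None = None
    sd_f_c: np.ndarray | None = None
    samples: np.ndarray | None = None  # (R, n_grid) per-path Z, if kept
    mean_leaps: float = math.nan

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "mean_Z": self.mean,
                "sd_Z": self.sd,
                "se_Z": self.se,
                "paths": self.R,
            }
        )


def observable_weights(net: ReactionNetwork, f) -> np.ndarray:
    """Resolve an observable (species index, name, or weight vector) to a
    linear-combination weight vector."""
    if isinstance(f, str):
        f = net.species_index(f)
    if np.isscalar(f):
        w = np.zeros(net.N)
        w[int(f)] = 1.0
        return w
    w = np.asarray(f, dtype=float)
    if w.shape != (net.N,):
        raise ValueError("observable weight vector must have length N")
    return w


def _stochastic_round(U: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Unbiased randomised rounding: up with probability frac(U)."""
    U = np.maximum(U, 0.0)
    base = np.floor(U)
    return (base + (u < U - base)).astype(np.int64)


def draw_increments(
    a_c: np.ndarray,
    a_ch: np.ndarray,
    ncr: np.ndarray,
    tau: float,
    rng: np.random.Generator,
    use_means: bool = False,
) -> PoissonIncrements:
    """Sample the shared/residual Poisson counts over non-critical channels."""
    ac = a_c[ncr]
    ah = a_ch[ncr]
    m = np.minimum(ac, ah)
    rates = np.concatenate((m, ac - m, ah - m))
    np.maximum(rates, 0.0, out=rates)
    if use_means:
        counts = rates * tau
    else:
        counts = rng.poisson(rates * tau).astype(float)
    n = m.shape[0]
    return PoissonIncrements(m, counts[:n], counts[n:2 * n], counts[2 * n:])


def cit_coupled_leap(
    net_c: ReactionNetwork,
    net_ch: ReactionNetwork,
    x_c: np.ndarray,
    x_ch: np.ndarray,
    tau: float,
    partition: ReactionPartition,
    rng: np.random.Generator,
    controls: LeapControls,
    use_means: bool = False,
) -> tuple[np.ndarray, np.ndarray, ImplicitSolveReport, ImplicitSolveReport, bool]:
    """One coupled implicit leap over the non-critical channels.

    Solves the two implicit systems (shared increments, separate unknowns)
    independently by Newton, then rounds and clamps.  Returns
    (x_c', x_ch', report_c, report_ch, ok) where ok is False when either
    solve failed or rounding produced a negative population — the caller
    halves tau, redraws and retries.
    """
    ncr = partition.ncr
    a_c = net_c.propensities(x_c)
    a_ch = net_ch.propensities(x_ch)
    inc = draw_increments(a_c, a_ch, ncr, tau, rng, use_means=use_means)
    rep_c = solve_implicit_state(
        net_c, x_c, tau, inc.P1 + inc.P2, mask=ncr,
        tol=controls.newton_tol, max_iter=controls.max_newton_iter,
    )
    rep_ch = solve_implicit_state(
        net_ch, x_ch, tau, inc.P1 + inc.P3, mask=ncr,
        tol=controls.newton_tol, max_iter=controls.max_newton_iter,
    )
    if not (rep_c.converged and rep_ch.converged):
        return x_c, x_ch, rep_c, rep_ch, False
    sol_c = rep_c.solution
    sol_h = rep_ch.solution
    if np.any(sol_c < -0.5) or np.any(sol_h < -0.5):
        return x_c, x_ch, rep_c, rep_ch, False
    # Stochastic rounding with one shared uniform per species: the coupled
    # difference between the legs is typically far below one molecule, and
    # deterministic nearest rounding re-injects quantisation error
    # (correlated with the shared Poisson draws) into exactly the signal
    # the estimator divides by h.  E[round(U)] = U removes that bias; the
    # shared uniform keeps the legs identical bitwise when h = 0 and acts
    # as a common random number for the quantisation itself.
    u = rng.random(sol_c.shape[0])
    xc_new = _stochastic_round(sol_c, u)
    xh_new = _stochastic_round(sol_h, u)
    return xc_new, xh_new, rep_c, rep_ch, True


def _apply_firing(x: np.ndarray, net: ReactionNetwork, j: int | None) -> np.ndarray | None:
    """Apply one critical firing; None signals a negative population."""
    if j is None:
        return x
    x_new = x + net.nu[:, j]
    if np.any(x_new < 0):
        return None
    return x_new


def cit_path(
    net: ReactionNetwork,
    param_index: int,
    h: float,
    x0: np.ndarray,
    T: float,
    controls: LeapControls,
    rng: np.random.Generator,
    grid: OutputGrid,
    f=0,
    use_means: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """One coupled CIT sample path.

    Per step: propensities on both legs; partial-equilibrium flags from the
    nominal leg applied to both; shared critical partition; non-critical
    candidates tau1 and critical candidates tau2 (fresh exponentials) per
    leg.  The step is the smallest of the four candidates; a critical
    reaction fires only when a tau2 attains it (nominal, perturbed, or —
    on an exact tie — both, selected with one shared uniform).  The coupled
    implicit leap then advances the non-critical channels and any critical
    firing is applied on top.  Returns (Z, f_c, f_h, n_leaps) on the grid.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    net_ch = net.with_perturbed_rate(param_index, h)
    w = observable_weights(net, f)
    x_c = np.asarray(x0, dtype=np.int64).copy()
    x_ch = x_c.copy()
    t = 0.0
    times = grid.times
    n = grid.n_points
    f_c = np.empty(n)
    f_h = np.empty(n)
    gi = 0
    n_leaps = 0
    tiny = _REL_EPS * max(T, 1.0)

    while t < T - tiny:
        a_c = net.propensities(x_c)
        a_ch = net_ch.propensities(x_ch)
        pe = partial_equilibrium_flags(net, a_c, controls.delta)
        eq_mask = equilibrium_reaction_mask(net, pe)
        part = classify_critical(
            net, x_c, x_ch, a_c, a_ch, controls.n_c, eq_mask
        )
        if not (part.crit.any() or part.ncr.any()):
            break  # nothing can fire: freeze to T
        tau1_c = tau_noncritical(net, x_c, a_c, part, controls.epsilon)
        tau1_h = tau_noncritical(net_ch, x_ch, a_ch, part, controls.epsilon)
        tau2_c = tau_critical(a_c, part, rng.random())
        tau2_h = tau_critical(a_ch, part, rng.random())
        tau1 = min(tau1_c, tau1_h)
        tau2 = min(tau2_c, tau2_h)

        fire_c: int | None = None
        fire_h: int | None = None
        if tau1 < tau2:
            tau = tau1
        elif math.isfinite(tau2):
            tau = tau2
            xi2 = rng.random()
            if tau2_c < tau2_h:
                fire_c = select_critical_reaction(part, a_c, xi2)
            elif tau2_h < tau2_c:
                fire_h = select_critical_reaction(part, a_ch, xi2)
            else:
                fire_c = select_critical_reaction(part, a_c, xi2)
                fire_h = select_critical_reaction(part, a_ch, xi2)
        else:
            # no finite candidate: only unconstrained channels remain,
            # leap straight to the horizon
            tau = T - t
        # clamp the leap to the next output time (and the horizon): the
        # state of a leap method is only defined at step boundaries, so
        # requested grid times must be landed on exactly; an interrupted
        # critical clock restarts without bias (exponential memorylessness)
        while gi < n and times[gi] <= t + tiny:
            f_c[gi] = w @ x_c
            f_h[gi] = w @ x_ch
            gi += 1
        t_goal = times[gi] if gi < n else T
        t_goal = min(t_goal, T)
        clamped = t + tau >= t_goal - tiny
        if clamped:
            tau = t_goal - t
            fire_c = fire_h = None  # the critical event lies beyond t_goal

        # attempt the step, halving tau (and cancelling the critical
        # firing, whose event time is then no longer reached) on failure
        tau_try = tau
        for attempt in range(controls.max_step_retries + 1):
            xc_new, xh_new, rep_c, rep_ch, ok = cit_coupled_leap(
                net, net_ch, x_c, x_ch, tau_try, part, rng, controls,
                use_means=use_means,
            )
            if ok:
                xc_fin = _apply_firing(xc_new, net, fire_c)
                xh_fin = _apply_firing(xh_new, net_ch, fire_h)
                if xc_fin is not None and xh_fin is not None:
                    break
            tau_try *= 0.5
            clamped = False
            fire_c = fire_h = None
        else:
            raise PathAbortedError(
                f"step at t={t:.6g} failed after "
                f"{controls.max_step_retries} retries"
            )

        t_next = t_goal if clamped else t + tau_try
        while gi < n and times[gi] < t_next:
            f_c[gi] = w @ x_c
            f_h[gi] = w @ x_ch
            gi += 1
        x_c, x_ch = xc_fin, xh_fin
        t = t_next
        n_leaps += 1

    while gi < n:
        f_c[gi] = w @ x_c
        f_h[gi] = w @ x_ch
        gi += 1
    Z = (f_h - f_c) / h if h > 0 else np.zeros(n)
    return Z, f_c, f_h, n_leaps


def implicit_tau_path(
    net: ReactionNetwork,
    x0: np.ndarray,
    T: float,
    controls: LeapControls,
    rng: np.random.Generator,
    grid: OutputGrid,
) -> tuple[np.ndarray, int]:
    """Single-path adaptive implicit tau-leaping trajectory on the grid.

    Same partial-equilibrium / critical machinery as the coupled path but
    for one trajectory: tau = min(tau1, tau2), with a critical firing when
    tau2 attains the minimum.  Returns (states, n_leaps).
    """
    x = np.asarray(x0, dtype=np.int64).copy()
    t = 0.0
    times = grid.times
    n = grid.n_points
    out = np.empty((n, net.N), dtype=np.int64)
    gi = 0
    n_leaps = 0
    tiny = _REL_EPS * max(T, 1.0)

    while t < T - tiny:
        a = net.propensities(x)
        pe = partial_equilibrium_flags(net, a, controls.delta)
        eq_mask = equilibrium_reaction_mask(net, pe)
        part = classify_critical(net, x, x, a, a, controls.n_c, eq_mask)
        if not (part.crit.any() or part.ncr.any()):
            break
        tau1 = tau_noncritical(net, x, a, part, controls.epsilon)
        tau2 = tau_critical(a, part, rng.random())
        fire: int | None = None
        if tau1 < tau2:
            tau = tau1
        elif math.isfinite(tau2):
            tau = tau2
            fire = select_critical_reaction(part, a, rng.random())
        else:
            tau = T - t
        # land exactly on output times (see cit_path)
        while gi < n and times[gi] <= t + tiny:
            out[gi] = x
            gi += 1
        t_goal = min(times[gi] if gi < n else T, T)
        clamped = t + tau >= t_goal - tiny
        if clamped:
            tau = t_goal - t
            fire = None

        tau_try = tau
        for attempt in range(controls.max_step_retries + 1):
            a_now = net.propensities(x)[part.ncr]
            K = rng.poisson(a_now * tau_try).astype(float)
            rep = solve_implicit_state(
                net, x, tau_try, K, mask=part.ncr,
                tol=controls.newton_tol, max_iter=controls.max_newton_iter,
            )
            if rep.converged:
                x_new, negative = round_state(rep.solution)
                if not negative:
                    x_fin = _apply_firing(x_new, net, fire)
                    if x_fin is not None:
                        break
            tau_try *= 0.5
            clamped = False
            fire = None
        else:
            raise PathAbortedError(
                f"step at t={t:.6g} failed after "
                f"{controls.max_step_retries} retries"
            )

        t_next = t_goal if clamped else t + tau_try
        while gi < n and times[gi] < t_next:
            out[gi] = x
            gi += 1
        x = x_fin
        t = t_next
        n_leaps += 1

    while gi < n:
        out[gi] = x
        gi += 1
    return out, n_leaps


# ----------------------------------------------------------------------
# ensemble driver
# ----------------------------------------------------------------------
def estimate_sensitivity(
    net: ReactionNetwork,
    param_index: int | str,
    h: float,
    x0: np.ndarray,
    T: float,
    controls: LeapControls | None = None,
    R: int = 1000,
    seed: int = 0,
    grid: OutputGrid | None = None,
    method: str = "cit",
    f=0,
    keep_samples: bool = False,
    max_abort_fraction: float = 0.01,
) -> SensitivitySeries:
    """Ensemble finite-difference sensitivity estimate.

    ``method`` is one of

    - ``"cit"``: coupled adaptive implicit tau-leaping paths;
    - ``"cfd"``: exact coupled next-reaction paths;
    - ``"implicit-fd"``: uncoupled finite difference from independent
      adaptive implicit-tau ensembles at c and c + h (variance baseline);
    - ``"ssa-fd"``: uncoupled finite difference from independent exact
      ensembles.

    Deterministic given ``seed``.  Paths that exhaust their retry budget
    are excluded and counted; more than ``max_abort_fraction`` aborted
    paths raises (mis-set controls).
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    if isinstance(param_index, str):
        param_index = net.reaction_index(param_index)
    controls = controls or LeapControls()
    grid = grid or OutputGrid(0.0, T, 2)
    streams = RngStreams(seed)
    w = observable_weights(net, f)
    n = grid.n_points

    Z_rows = []
    fc_rows = []
    fh_rows = []
    leaps = []
    aborted = 0
    net_ch = net.with_perturbed_rate(param_index, h)

    for r in range(R):
        rng = streams.substream(r)
        try:
            if method == "cit":
                Z, fc, fh, nl = cit_path(
                    net, param_index, h, x0, T, controls, rng, grid, f=f
                )
                leaps.append(nl)
            elif method == "cfd":
                xc, xh = coupled_next_reaction_paths(
                    net, param_index, h, x0, T, rng, grid
                )
                fc = xc @ w
                fh = xh @ w
                Z = (fh - fc) / h if h > 0 else np.zeros(n)
            elif method == "implicit-fd":
                rng2 = streams.substream(r, 1)
                xc, nl1 = implicit_tau_path(net, x0, T, controls, rng, grid)
                xh, nl2 = implicit_tau_path(net_ch, x0, T, controls, rng2, grid)
                fc = xc @ w
                fh = xh @ w
                Z = (fh - fc) / h if h > 0 else np.zeros(n)
                leaps.append(nl1 + nl2)
            elif method == "ssa-fd":
                rng2 = streams.substream(r, 1)
                xc = ssa_path(net, x0, T, rng, grid)
                xh = ssa_path(net_ch, x0, T, rng2, grid)
                fc = xc @ w
                fh = xh @ w
                Z = (fh - fc) / h if h > 0 else np.zeros(n)
            else:
                raise ValueError(f"unknown method {method!r}")
        except PathAbortedError:
            aborted += 1
            continue
        Z_rows.append(Z)
        fc_rows.append(fc)
        fh_rows.append(fh)

    if aborted > max_abort_fraction * R:
        raise RuntimeError(
            f"{aborted}/{R} paths aborted; adjust leap controls"
        )
    Zm = np.array(Z_rows)
    R_eff = Zm.shape[0]
    mean = Zm.mean(axis=0)
    sd = Zm.std(axis=0, ddof=1)
    return SensitivitySeries(
        times=grid.times,
        mean=mean,
        sd=sd,
        se=sd / math.sqrt(R_eff),
        R=R_eff,
        method=method,
        aborted=aborted,
        mean_f_c=np.array(fc_rows).mean(axis=0),
        mean_f_ch=np.array(fh_rows).mean(axis=0),
        sd_f_c=np.array(fc_rows).std(axis=0, ddof=1),
        samples=Zm if keep_samples else None,
        mean_leaps=float(np.mean(leaps)) if leaps else math.nan,
    )
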