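"""Explicit and implicit tau-leap steps and the Newton solver behind the
implicit update.

The explicit step advances x by independent Poisson firing counts with
means a_j(x) * tau.  The implicit step is semi-implicit: only the mean part
of each Poisson term is evaluated at the end-of-step state, i.e. it solves

    U = x + sum_j nu_j * [(a_j(U) - a_j(x)) * tau + P_j],
    P_j ~ Poisson(a_j(x) * tau),

which reduces to one backward-Euler step of the reaction-rate equations
when the Poisson draws are replaced by their means.  The continuous Newton
solution is rounded componentwise to the nearest integer and clamped at
zero; rounding/clamping policy is an implementation choice following
common implicit-leaping practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork


class NegativePopulationError(RuntimeError):
    """An explicit or implicit step produced a negative copy number."""


class NewtonConvergenceError(RuntimeError):
    """Newton failed to converge within the iteration budget."""


@dataclass
class ImplicitSolveReport:
    converged: bool
    iterations: int
    residual_norm: float
    solution: np.ndarray  # continuous pre-rounding state
    clamped: bool = False


def explicit_tau_step(
    net: ReactionNetwork,
    x: np.ndarray,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One explicit Poisson leap; raises on negative resulting populations."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = net.propensities(x)
    K = rng.poisson(a * tau)
    x_new = np.asarray(x, dtype=np.int64) + net.nu @ K
    if np.any(x_new < 0):
        raise NegativePopulationError(
            f"explicit step tau={tau:.3g} produced {x_new.tolist()}"
        )
    return x_new


def solve_implicit_state(
    net: ReactionNetwork,
    x: np.ndarray,
    tau: float,
    K: np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 0.01,
    max_iter: int = 50,
) -> ImplicitSolveReport:
    """Newton solve of U = x + sum_{j in mask} nu_j [(a_j(U)-a_j(x)) tau + K_j].

    ``K`` holds the (already drawn) firing-count terms per masked channel.
    Uses the analytic propensity Jacobian, warm start at x, and step
    halving when the residual norm increases.  Convergence is declared when
    the infinity norm of the Newton update drops below ``tol``.
    """
    x = np.asarray(x, dtype=float)
    if mask is None:
        mask = np.ones(net.M, dtype=bool)
    cache = getattr(net, "_mask_cache", None)
    if cache is None:
        cache = net._mask_cache = {}
    key = mask.tobytes()
    hit = cache.get(key)
    if hit is None:
        midx = np.flatnonzero(mask)
        hit = cache[key] = (midx, net.nu[:, midx].astype(float))
    midx, nu_sub = hit
    a_x = net.propensities(x)[midx]
    base = x + nu_sub @ K  # constant part of the fixed point map
    drift0 = nu_sub @ a_x * tau

    eye = np.eye(net.N)

    def residual(U):
        aU = net.propensities(np.maximum(U, 0.0))[midx]
        return U - base - nu_sub @ aU * tau + drift0

    U = x.copy()
    F = residual(U)
    norm_F = float(F @ F)  # squared norms suffice for the comparisons
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = eye - tau * (
            nu_sub @ net.propensity_jacobian(np.maximum(U, 0.0))[midx, :]
        )
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            break
        # damped update: halve the step while the residual grows
        lam = 1.0
        for _ in range(5):
            U_new = U + lam * step
            F_new = residual(U_new)
            n_new = float(F_new @ F_new)
            if n_new <= norm_F or lam <= 1.0 / 16:
                break
            lam *= 0.5
        U, F, norm_F = U_new, F_new, n_new
        if np.max(np.abs(lam * step)) < tol:
            converged = True
            break
    return ImplicitSolveReport(
        converged=converged,
        iterations=it,
        residual_norm=math.sqrt(norm_F),
        solution=U,
    )


def round_state(U: np.ndarray) -> tuple[np.ndarray, bool]:
    """Round the continuous solution to nearest integers, clamp at zero.

    Returns (state, went_negative) where went_negative reports whether any
    component rounded below zero before clamping.
    """
    r = np.rint(U).astype(np.int64)
    negative = bool(np.any(r < 0))
    np.maximum(r, 0, out=r)
    return r, negative


def implicit_tau_step(
    net: ReactionNetwork,
    x: np.ndarray,
    tau: float,
    rng: np.random.Generator,
    tol: float = 0.01,
    max_iter: int = 50,
    use_means: bool = False,
) -> tuple[np.ndarray, ImplicitSolveReport]:
    """One implicit leap over all channels.

    ``use_means`` replaces the Poisson draws by their means, turning the
    step into deterministic backward Euler (test/diagnostic hook).  Raises
    NewtonConvergenceError when the solve does not converge; the caller
    owns the retry policy (halve tau and redraw).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = net.propensities(x)
    K = a * tau if use_means else rng.poisson(a * tau).astype(float)
    report = solve_implicit_state(net, x, tau, K, tol=tol, max_iter=max_iter)
    if not report.converged:
        raise NewtonConvergenceError(
            f"Newton stalled after {report.iterations} iterations "
            f"(|F|={report.residual_norm:.3g}, tau={tau:.3g})"
        )
    x_new, negative = round_state(report.solution)
    report.clamped = negative
    return x_new, report
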