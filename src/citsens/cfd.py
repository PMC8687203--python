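"""Coupled finite-difference (CFD) baseline estimator.

Exact coupled paths via the next-reaction random-time-change coupling; no
leaping is involved, so each leg is marginally an exact sample of the
master equation.  This makes the CFD both the accuracy reference and the
cost baseline for the coupled implicit-tau estimator.
"""

from __future__ import annotations

import numpy as np

from .network import ReactionNetwork
from .ssa import OutputGrid, coupled_next_reaction_paths
from .cit import SensitivitySeries, estimate_sensitivity, observable_weights


def cfd_path(
    net: ReactionNetwork,
    param_index: int,
    h: float,
    x0: np.ndarray,
    T: float,
    rng: np.random.Generator,
    grid: OutputGrid,
    f=0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One coupled exact sample path; returns (Z, f_c, f_h) on the grid."""
    w = observable_weights(net, f)
    xc, xh = coupled_next_reaction_paths(net, param_index, h, x0, T, rng, grid)
    f_c = xc @ w
    f_h = xh @ w
    Z = (f_h - f_c) / h if h > 0 else np.zeros(grid.n_points)
    return Z, f_c, f_h


def cfd_estimate(
    net: ReactionNetwork,
    param_index: int | str,
    h: float,
    x0: np.ndarray,
    T: float,
    R: int,
    seed: int,
    grid: OutputGrid | None = None,
    f=0,
    keep_samples: bool = False,
) -> SensitivitySeries:
    """Ensemble CFD estimate (thin wrapper over the shared driver)."""
    return estimate_sensitivity(
        net, param_index, h, x0, T, R=R, seed=seed, grid=grid,
        method="cfd", f=f, keep_samples=keep_samples,
    )
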