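"""Reaction-network representation and propensity evaluation.

A well-stirred biochemical system is a set of species S_1..S_N and reaction
channels R_1..R_M.  Each channel j carries a stoichiometric change vector
nu_j and a propensity a_j(x): a_j(x) dt is the probability that channel j
fires once in [t, t+dt) given state x.  Supported propensity forms are
stochastic mass action up to third order (combinatorial counting of
reactant tuples) and a Hill-type repression form

    a_j(x) = scale * c_j / (1 + x_r ** beta)

used for repressor-controlled transcription.  Analytic state derivatives of
every propensity are available, which keeps the Newton iterations of the
implicit leap solvers exact.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MASS_ACTION = "mass_action"
HILL_REPRESSION = "hill_repression"


class ConfigurationError(ValueError):
    """Raised for malformed network definitions or model files."""


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``reactants`` and ``products`` map species index -> multiplicity.
    ``rate_constant`` is the stochastic rate constant c_j (for the Hill form
    it is the maximal propensity, i.e. the numerator).  ``scaled`` marks
    channels whose propensity is additionally multiplied by the network's
    global scale factor k (the stiffness knob of the toggle-switch model).
    """

    name: str
    reactants: tuple[tuple[int, int], ...]
    products: tuple[tuple[int, int], ...]
    rate_constant: float
    form: str = MASS_ACTION
    hill_repressor: int = -1
    hill_exponent: float = 1.0
    scaled: bool = False

    def __post_init__(self):
        if self.form not in (MASS_ACTION, HILL_REPRESSION):
            raise ConfigurationError(f"unknown propensity form {self.form!r}")
        if self.rate_constant < 0:
            raise ConfigurationError("rate constants must be >= 0")
        order = sum(m for _, m in self.reactants)
        if self.form == MASS_ACTION and order > 3:
            raise ConfigurationError("mass-action order must be <= 3")
        if self.form == HILL_REPRESSION and self.hill_repressor < 0:
            raise ConfigurationError("hill_repression needs a repressor index")

    @property
    def order(self) -> int:
        """Total reaction order (sum of reactant multiplicities)."""
        return sum(m for _, m in self.reactants)


@dataclass
class SystemState:
    """Copy-number vector x at time t."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x)
        if np.any(self.x < 0) or self.t < 0:
            raise ValueError("state requires x >= 0 and t >= 0")

    def copy(self) -> "SystemState":
        return SystemState(self.x.copy(), self.t)


class ReactionNetwork:
    """Species, stoichiometry, propensity definitions and rate constants.

    Parameters
    ----------
    species_names
        Identifiers of the N species.
    reactions
        The M reaction channels in index order.
    reversible_pairs
        (j_forward, j_backward) index pairs; each pair must have exactly
        opposite net stoichiometry and a reaction may appear in at most one
        pair.  Pairs are what the partial-equilibrium test operates on.
    scale
        Global multiplier k applied to every reaction flagged ``scaled``.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        reactions: Sequence[Reaction],
        reversible_pairs: Sequence[tuple[int, int]] = (),
        scale: float = 1.0,
    ):
        if scale < 0:
            raise ConfigurationError("scale factor must be >= 0")
        self.species_names = list(species_names)
        self.reactions = list(reactions)
        self.reversible_pairs = [tuple(p) for p in reversible_pairs]
        self.scale = float(scale)
        self.N = len(self.species_names)
        self.M = len(self.reactions)

        self.nu = np.zeros((self.N, self.M), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for i, m in r.reactants:
                self.nu[i, j] -= m
            for i, m in r.products:
                self.nu[i, j] += m

        seen: set[int] = set()
        for jf, jb in self.reversible_pairs:
            if np.any(self.nu[:, jf] != -self.nu[:, jb]):
                raise ConfigurationError(
                    f"reversible pair ({jf},{jb}) is not stoichiometrically inverse"
                )
            for j in (jf, jb):
                if j in seen:
                    raise ConfigurationError(
                        f"reaction {j} appears in more than one reversible pair"
                    )
                seen.add(j)

        # effective per-reaction multiplier (1 or k)
        self._mult = np.array(
            [self.scale if r.scaled else 1.0 for r in self.reactions]
        )
        self._c = np.array([r.rate_constant for r in self.reactions])
        self._evaluate = None  # lazily compiled scalar evaluator
        self._consumed = None  # lazily built per-reaction consumption info
        # per-reaction mass-action denominator prod(multiplicity!)
        self._denom = np.array(
            [
                math.prod(math.factorial(m) for _, m in r.reactants)
                if r.form == MASS_ACTION
                else 1.0
                for r in self.reactions
            ]
        )

    # ------------------------------------------------------------------
    # parameter perturbation
    # ------------------------------------------------------------------
    def with_perturbed_rate(self, param_index: int, h: float) -> "ReactionNetwork":
        """Copy of the network with c_j replaced by c_j + h for one reaction."""
        if not 0 <= param_index < self.M:
            raise ConfigurationError(f"no reaction with index {param_index}")
        reactions = list(self.reactions)
        r = reactions[param_index]
        reactions[param_index] = Reaction(
            r.name, r.reactants, r.products, r.rate_constant + h,
            r.form, r.hill_repressor, r.hill_exponent, r.scaled,
        )
        return ReactionNetwork(
            self.species_names, reactions, self.reversible_pairs, self.scale
        )

    def reaction_index(self, name: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.name == name:
                return j
        raise ConfigurationError(f"no reaction named {name!r}")

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ConfigurationError(f"no species named {name!r}") from None

    # ------------------------------------------------------------------
    # propensities
    # ------------------------------------------------------------------
    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Propensity vector a(x), length M.

        Mass action follows combinatorial counting: first order c*x_i,
        homo-dimerisation c*x_i*(x_i-1)/2, heterogeneous second order
        c*x_i*x_j, third order with falling factorials divided by the
        multiplicity factorials.  (States with fewer copies than a
        multiplicity requires give zero ways to pick the tuple, hence
        zero propensity.)
        """
        xs = x.tolist() if isinstance(x, np.ndarray) else list(x)
        if xs and min(xs) < 0:
            raise ValueError("negative copy numbers in propensity evaluation")
        if self._evaluate is None:
            self._evaluate = self.compiled_propensities()
        return np.array(self._evaluate(xs, [0.0] * self.M))

    def propensities_batch(self, X: np.ndarray) -> np.ndarray:
        """Vectorised propensities for a batch of states (n, N) -> (n, M)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        A = np.empty((n, self.M))
        for j, r in enumerate(self.reactions):
            if r.form == MASS_ACTION:
                v = np.ones(n)
                for i, m in r.reactants:
                    xi = X[:, i]
                    for q in range(m):
                        v = v * (xi - q)
                A[:, j] = self._mult[j] * self._c[j] * v / self._denom[j]
            else:
                xr = X[:, r.hill_repressor]
                A[:, j] = self._mult[j] * self._c[j] / (1.0 + xr ** r.hill_exponent)
        np.maximum(A, 0.0, out=A)
        return A

    def _compile_jacobian(self):
        """Precompute the sparse structure of da_j/dx_i for scalar
        evaluation (one entry per reaction/reactant-species pair)."""
        entries = []
        for j, r in enumerate(self.reactions):
            if r.form == MASS_ACTION:
                pref = self._mult[j] * self._c[j] / self._denom[j]
                for i, m in r.reactants:
                    others = tuple(
                        (i2, q)
                        for i2, m2 in r.reactants
                        if i2 != i
                        for q in range(m2)
                    )
                    entries.append((0, j, i, pref, others, m, 0.0))
            else:
                entries.append(
                    (1, j, r.hill_repressor,
                     self._mult[j] * self._c[j], (), 0, r.hill_exponent)
                )
        return entries

    def propensity_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic partials da_j/dx_i as an (M, N) matrix, x continuous."""
        entries = getattr(self, "_jac_entries", None)
        if entries is None:
            entries = self._jac_entries = self._compile_jacobian()
        xs = x.tolist() if isinstance(x, np.ndarray) else list(x)
        J = np.zeros((self.M, self.N))
        for kind, j, i, pref, others, m, beta in entries:
            if kind == 0:
                v = pref
                for i2, q in others:
                    v *= xs[i2] - q
                xi = xs[i]
                # derivative of the falling factorial prod_{q<m}(xi - q)
                if m == 1:
                    pass
                elif m == 2:
                    v *= 2.0 * xi - 1.0
                else:
                    v *= (3.0 * xi - 6.0) * xi + 2.0
                J[j, i] = v
            else:
                xr = xs[i]
                if xr == 0.0 and beta > 1:
                    continue
                if xr == 0.0:
                    J[j, i] = -pref
                else:
                    J[j, i] = (
                        -pref * beta * xr ** (beta - 1)
                        / (1.0 + xr ** beta) ** 2
                    )
        return J

    def compiled_propensities(self):
        """Scalar-arithmetic propensity evaluator for tight event loops.

        Returns ``evaluate(x, out)`` filling the list ``out`` (length M)
        from a sequence ``x`` of copy numbers.  Semantics identical to
        :meth:`propensities`; numpy dispatch overhead dominates exact
        simulation at these small M, so the hot loops use this instead.
        """
        entries = []
        for j, r in enumerate(self.reactions):
            ceff = self._mult[j] * self._c[j]
            if r.form == MASS_ACTION:
                slots = tuple(
                    (i, q) for i, m in r.reactants for q in range(m)
                )
                entries.append((0, ceff / self._denom[j], slots, 0, 0.0))
            else:
                entries.append(
                    (1, ceff, (), r.hill_repressor, r.hill_exponent)
                )

        def evaluate(x, out):
            for j, (kind, c, slots, rep, beta) in enumerate(entries):
                if kind == 0:
                    v = c
                    for i, q in slots:
                        v *= x[i] - q
                    out[j] = v if v > 0.0 else 0.0
                else:
                    out[j] = c / (1.0 + x[rep] ** beta)
            return out

        return evaluate

    def consumed_species(self) -> list[list[tuple[int, int]]]:
        """Per reaction, (species, |nu_ij|) for every consumed species."""
        if self._consumed is None:
            self._consumed = [
                [
                    (int(i), int(-self.nu[i, j]))
                    for i in np.flatnonzero(self.nu[:, j] < 0)
                ]
                for j in range(self.M)
            ]
        return self._consumed

    @property
    def nu_sparse(self) -> list[list[tuple[int, int]]]:
        """Per-reaction nonzero stoichiometry as (species, delta) pairs."""
        return [
            [(int(i), int(self.nu[i, j])) for i in np.flatnonzero(self.nu[:, j])]
            for j in range(self.M)
        ]

    # ------------------------------------------------------------------
    # reaction-order bookkeeping for the leap-size rules
    # ------------------------------------------------------------------
    def species_reaction_orders(
        self, reaction_subset: Sequence[int] | np.ndarray | None = None
    ) -> dict[int, tuple[int, int]]:
        """Highest reaction order per species over a subset of channels.

        Returns ``{species index: (psi_i, mult_i)}`` where psi_i is the
        highest total order among subset reactions in which species i is a
        reactant and mult_i is the largest multiplicity with which it
        appears in a reaction attaining psi_i (mult >= 2 triggers the
        homo-reactant corrections of the leap-exponent rules).  Species that
        are never reactants within the subset are absent.
        """
        if reaction_subset is None:
            subset = range(self.M)
        else:
            arr = np.asarray(reaction_subset)
            if arr.dtype == bool:
                subset = np.flatnonzero(arr)
            else:
                subset = arr
        out: dict[int, tuple[int, int]] = {}
        for j in subset:
            r = self.reactions[int(j)]
            order = r.order
            for i, m in r.reactants:
                psi, mult = out.get(i, (0, 0))
                if order > psi:
                    out[i] = (order, m)
                elif order == psi and m > mult:
                    out[i] = (psi, m)
        return out


# ----------------------------------------------------------------------
# plain-text model files
# ----------------------------------------------------------------------
# Grammar (one declaration per line, '#' comments):
#   species <name> <initial count>
#   reaction <name>: <k1 S1 + k2 S2 | 0> -> <...> ; rate=<float>
#            [; hill repressor=<species> exponent=<float>] [; scaled]
#   reversible <forward name> <backward name>
#   scale <float>
_SIDE_TERM = re.compile(r"^(?:(\d+)\s*\*?\s*)?([A-Za-z_]\w*)$")


def _parse_side(text: str, index: dict[str, int]) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if text in ("", "0", "@"):
        return ()
    terms: dict[int, int] = {}
    for part in text.split("+"):
        m = _SIDE_TERM.match(part.strip())
        if not m:
            raise ConfigurationError(f"cannot parse reaction side term {part!r}")
        mult = int(m.group(1) or 1)
        name = m.group(2)
        if name not in index:
            raise ConfigurationError(f"unknown species {name!r}")
        terms[index[name]] = terms.get(index[name], 0) + mult
    return tuple(sorted(terms.items()))


def parse_model(text: str) -> tuple[ReactionNetwork, np.ndarray]:
    """Parse the plain-text model format; returns (network, x0)."""
    species: list[str] = []
    x0: list[int] = []
    index: dict[str, int] = {}
    raw_reactions: list[tuple[str, str, dict]] = []
    reversible_names: list[tuple[str, str]] = []
    scale = 1.0

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            head, rest = line.split(None, 1)
        except ValueError:
            raise ConfigurationError(f"line {lineno}: cannot parse {line!r}")
        if head == "species":
            name, count = rest.split()
            index[name] = len(species)
            species.append(name)
            x0.append(int(count))
        elif head == "reaction":
            name, body = rest.split(":", 1)
            parts = [p.strip() for p in body.split(";")]
            arrow = parts[0]
            opts = parts[1:]
            lhs, rhs = arrow.split("->")
            kw: dict = {"form": MASS_ACTION, "scaled": False}
            for opt in opts:
                if opt == "scaled":
                    kw["scaled"] = True
                elif opt.startswith("rate"):
                    kw["rate"] = float(opt.split("=", 1)[1])
                elif opt.startswith("hill"):
                    kw["form"] = HILL_REPRESSION
                    for token in opt.split()[1:]:
                        key, val = token.split("=")
                        if key == "repressor":
                            kw["repressor"] = val
                        elif key == "exponent":
                            kw["exponent"] = float(val)
                        else:
                            raise ConfigurationError(
                                f"line {lineno}: unknown hill option {key!r}"
                            )
                else:
                    raise ConfigurationError(
                        f"line {lineno}: unknown option {opt!r}"
                    )
            if "rate" not in kw:
                raise ConfigurationError(f"line {lineno}: reaction needs rate=")
            raw_reactions.append((name.strip(), lhs + "->" + rhs, kw))
        elif head == "reversible":
            f, b = rest.split()
            reversible_names.append((f, b))
        elif head == "scale":
            scale = float(rest)
        else:
            raise ConfigurationError(f"line {lineno}: unknown declaration {head!r}")

    reactions = []
    for name, arrow, kw in raw_reactions:
        lhs, rhs = arrow.split("->")
        reactions.append(
            Reaction(
                name,
                _parse_side(lhs, index),
                _parse_side(rhs, index),
                kw["rate"],
                form=kw["form"],
                hill_repressor=index[kw["repressor"]] if kw["form"] == HILL_REPRESSION else -1,
                hill_exponent=kw.get("exponent", 1.0),
                scaled=kw["scaled"],
            )
        )
    net = ReactionNetwork(species, reactions, scale=scale)
    pairs = [(net.reaction_index(f), net.reaction_index(b)) for f, b in reversible_names]
    return (
        ReactionNetwork(species, reactions, pairs, scale=scale),
        np.array(x0, dtype=np.int64),
    )


def format_model(net: ReactionNetwork, x0: np.ndarray) -> str:
    """Serialise a network back to the plain-text model format."""
    lines = []
    for name, c in zip(net.species_names, x0):
        lines.append(f"species {name} {int(c)}")
    if net.scale != 1.0:
        lines.append(f"scale {net.scale!r}")
    for r in net.reactions:
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(
                (f"{m} {net.species_names[i]}" if m > 1 else net.species_names[i])
                for i, m in terms
            )
        opts = [f"rate={r.rate_constant!r}"]
        if r.form == HILL_REPRESSION:
            opts.append(
                f"hill repressor={net.species_names[r.hill_repressor]}"
                f" exponent={r.hill_exponent!r}"
            )
        if r.scaled:
            opts.append("scaled")
        lines.append(
            f"reaction {r.name}: {side(r.reactants)} -> {side(r.products)} ; "
            + " ; ".join(opts)
        )
    for jf, jb in net.reversible_pairs:
        lines.append(
            f"reversible {net.reactions[jf].name} {net.reactions[jb].name}"
        )
    return "\n".join(lines) + "\n"
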