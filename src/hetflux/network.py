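"""Atom-transition metabolic networks and their flux-space parameterization.

A network is a set of metabolites (substrates, balanced internal pools, and
sinks) and reactions that carry every carbon of every reactant to a carbon of
a product.  Steady-state net fluxes live in the null space of the
stoichiometric matrix over the internal metabolites; a small set of free
fluxes (plus fixed/linear constraints) parameterizes that space exactly.

Reversible reactions additionally carry an exchange flux, stored on the
compactified scale ``xch01`` in [0, 1): the raw bidirectional rate is
``e = xch01 / (1 - xch01)``, so forward = max(net, 0) + e and
backward = max(-net, 0) + e.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy

__all__ = [
    "Metabolite",
    "Reaction",
    "AtomTransitionNetwork",
    "FluxState",
    "FreeFluxParameterization",
    "NetworkError",
    "parse_network",
    "stoichiometric_matrix",
    "free_flux_basis",
    "complete_fluxes",
]

ROLES = ("substrate", "internal", "sink")

BALANCE_TOL = 1e-9


class NetworkError(ValueError):
    """Raised for malformed network documents or infeasible flux algebra."""


@dataclass(frozen=True)
class Metabolite:
    name: str
    n_carbons: int
    role: str

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkError(f"metabolite {self.name}: negative carbon count")
        if self.role not in ROLES:
            raise NetworkError(f"metabolite {self.name}: unknown role {self.role!r}")


# One side of a reaction: ordered (metabolite, carbon-label string) instances.
# A metabolite occurring with stoichiometry 2 appears as two instances.
Side = tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class Reaction:
    """A reaction with an explicit carbon map.

    ``product_alternatives`` holds one or more equivalent right-hand sides;
    when a symmetric metabolite (succinate, fumarate) can react in two carbon
    orientations the reaction lists both, and each alternative carries
    ``1/len(product_alternatives)`` of the reaction's flux.
    """

    name: str
    reactants: Side
    product_alternatives: tuple[Side, ...]
    reversible: bool = False
    cofactors: dict[str, Fraction] = field(default_factory=dict)

    @property
    def products(self) -> Side:
        return self.product_alternatives[0]

    def carbon_count(self) -> int:
        return sum(len(lbl) for _, lbl in self.reactants)


@dataclass
class AtomTransitionNetwork:
    name: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    constraints: list[tuple[str, Fraction, str | None, Fraction]]
    #: (reaction, coeff_on_other, other_reaction_or_None, constant):
    #: v[reaction] = coeff * v[other] + constant
    free_net: list[str] = field(default_factory=list)
    free_xch: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def metabolite(self, name: str) -> Metabolite:
        return self.metabolites[name]

    def internal_names(self) -> list[str]:
        return [m.name for m in self.metabolites.values() if m.role == "internal"]

    def reaction_order(self) -> list[str]:
        return list(self.reactions)

    def validate(self) -> None:
        if not self.reactions:
            raise NetworkError("no reactions")
        for rxn in self.reactions.values():
            self._validate_reaction(rxn)
        produced: set[str] = set()
        consumed: set[str] = set()
        for rxn in self.reactions.values():
            for met, _ in rxn.reactants:
                consumed.add(met)
                if rxn.reversible:
                    produced.add(met)
            for met, _ in rxn.products:
                produced.add(met)
                if rxn.reversible:
                    consumed.add(met)
        for name in self.internal_names():
            if name not in produced or name not in consumed:
                raise NetworkError(
                    f"internal metabolite {name} is not both produced and consumed"
                )

    def _validate_reaction(self, rxn: Reaction) -> None:
        for met, lbl in rxn.reactants:
            self._check_instance(rxn.name, met, lbl)
        reactant_labels = [c for _, lbl in rxn.reactants for c in lbl]
        if len(set(reactant_labels)) != len(reactant_labels):
            raise NetworkError(f"reaction {rxn.name}: duplicate carbon label on LHS")
        counts0 = _side_counts(rxn.product_alternatives[0])
        for side in rxn.product_alternatives:
            for met, lbl in side:
                self._check_instance(rxn.name, met, lbl)
            product_labels = [c for _, lbl in side for c in lbl]
            if len(set(product_labels)) != len(product_labels):
                raise NetworkError(
                    f"reaction {rxn.name}: duplicate carbon label on RHS"
                )
            if sorted(product_labels) != sorted(reactant_labels):
                raise NetworkError(
                    f"reaction {rxn.name}: atom map is not a bijection "
                    f"(LHS carbons {sorted(reactant_labels)}, "
                    f"RHS carbons {sorted(product_labels)})"
                )
            if _side_counts(side) != counts0:
                raise NetworkError(
                    f"reaction {rxn.name}: alternative maps differ in stoichiometry"
                )

    def _check_instance(self, rname: str, met: str, lbl: str) -> None:
        if met not in self.metabolites:
            raise NetworkError(f"reaction {rname}: undeclared metabolite {met}")
        n = self.metabolites[met].n_carbons
        if len(lbl) != n:
            raise NetworkError(
                f"reaction {rname}: {met} has {n} carbons but map {lbl!r} "
                f"gives {len(lbl)}"
            )


def _side_counts(side: Side) -> dict[str, int]:
    counts: dict[str, int] = {}
    for met, _ in side:
        counts[met] = counts.get(met, 0) + 1
    return counts


@dataclass
class FluxState:
    """Net fluxes for every reaction plus compactified exchange fluxes."""

    net: dict[str, float]
    xch01: dict[str, float] = field(default_factory=dict)

    def exchange_raw(self, reaction: str) -> float:
        x = self.xch01.get(reaction, 0.0)
        return x / (1.0 - x)

    def forward(self, reaction: str) -> float:
        return max(self.net[reaction], 0.0) + self.exchange_raw(reaction)

    def backward(self, reaction: str) -> float:
        return max(-self.net[reaction], 0.0) + self.exchange_raw(reaction)

    def validate(self, net: AtomTransitionNetwork, tol: float = BALANCE_TOL) -> None:
        S, rows, cols = stoichiometric_matrix(net)
        v = np.array([self.net[r] for r in cols])
        resid = np.abs(S @ v)
        if resid.size and resid.max() > tol:
            worst = rows[int(np.argmax(resid))]
            raise NetworkError(
                f"stoichiometric balance violated at {worst}: |S.v| = {resid.max():.3g}"
            )
        for rname, rxn in net.reactions.items():
            if not rxn.reversible and self.net[rname] < -tol:
                raise NetworkError(f"irreversible reaction {rname} has negative net flux")
            if rname in self.xch01 and not (0.0 <= self.xch01[rname] < 1.0):
                raise NetworkError(f"{rname}: xch01 outside [0, 1)")
            if rname in self.xch01 and not rxn.reversible and self.xch01[rname] > 0:
                raise NetworkError(f"irreversible reaction {rname} has exchange flux")


@dataclass
class FreeFluxParameterization:
    """Exact linear map from free-flux values to the full net-flux vector.

    v_net = basis @ f_net + offset, in ``reaction_order``; exchange free
    fluxes pass through to FluxState.xch01 directly.
    """

    network: AtomTransitionNetwork
    free_net_names: list[str]
    free_xch_names: list[str]
    reaction_order: list[str]
    basis: np.ndarray  # (n_reactions, n_free_net)
    offset: np.ndarray  # (n_reactions,)
    bounds: dict[str, tuple[float, float]]

    @property
    def free_names(self) -> list[str]:
        return [f"{r}.net" for r in self.free_net_names] + [
            f"{r}.xch" for r in self.free_xch_names
        ]

    @property
    def n_free(self) -> int:
        return len(self.free_net_names) + len(self.free_xch_names)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free_names:
            b = self.bounds.get(name, (-np.inf, np.inf))
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def free_vector(self, state: FluxState) -> np.ndarray:
        vals = [state.net[r] for r in self.free_net_names]
        vals += [state.xch01.get(r, 0.0) for r in self.free_xch_names]
        return np.array(vals)


# ---------------------------------------------------------------------------
# parsing

_SECTIONS = ("METABOLITES", "REACTIONS", "COFACTORS", "CONSTRAINTS", "FREE")

_REACTION_RE = re.compile(r"^(\w+)\s*:\s*(.*?)->(.*?)(\s+rev)?$")
_INSTANCE_RE = re.compile(r"^(\w+)\s*(?:\(([A-Za-z]*)\))?$")
_CONSTRAINT_RE = re.compile(
    r"^(\w+)\.net\s*=\s*(?:([0-9.eE+-]+)\s*\*\s*(\w+)\.net\s*)?([+-]?[0-9.eE+]+[0-9eE.+-]*)?$"
)
_FREE_RE = re.compile(
    r"^(\w+)\.(net|xch)(?:\s+in\s+\[\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\])?$"
)


def parse_network(text: str, name: str = "network") -> AtomTransitionNetwork:
    """Parse the plain-text network format.

    Sections: ``METABOLITES`` (name, carbons, role), ``REACTIONS``
    (``R1: A (ab) -> B (a) + C (b) [rev]``, with ``|`` separating alternative
    right-hand sides for symmetric metabolites), ``COFACTORS``
    (``R1: NADH +1, ATP -2``), ``CONSTRAINTS`` (``R0.net = 1`` or
    ``Rb.net = 0.2 * Rbm.net``), ``FREE`` (``R1.net in [0, 1]``).
    ``#`` starts a comment; whitespace is insignificant.
    """
    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    constraints: list[tuple[str, Fraction, str | None, Fraction]] = []
    free_net: list[str] = []
    free_xch: list[str] = []
    bounds: dict[str, tuple[float, float]] = {}
    net_name = name

    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("NETWORK"):
            net_name = line.split(None, 1)[1] if " " in line else name
            continue
        if line in _SECTIONS:
            section = line
            continue
        try:
            if section == "METABOLITES":
                parts = line.split()
                if len(parts) != 3:
                    raise NetworkError("expected 'name carbons role'")
                mname, nc, role = parts
                if mname in metabolites:
                    raise NetworkError(f"duplicate metabolite {mname}")
                metabolites[mname] = Metabolite(mname, int(nc), role)
            elif section == "REACTIONS":
                rxn = _parse_reaction(line)
                if rxn.name in reactions:
                    raise NetworkError(f"duplicate reaction {rxn.name}")
                reactions[rxn.name] = rxn
            elif section == "COFACTORS":
                rname, spec = (s.strip() for s in line.split(":", 1))
                if rname not in reactions:
                    raise NetworkError(f"cofactors for undeclared reaction {rname}")
                cof = dict(reactions[rname].cofactors)
                for item in spec.split(","):
                    species, count = item.split()
                    cof[species] = cof.get(species, Fraction(0)) + Fraction(count)
                reactions[rname] = Reaction(
                    rname,
                    reactions[rname].reactants,
                    reactions[rname].product_alternatives,
                    reactions[rname].reversible,
                    cof,
                )
            elif section == "CONSTRAINTS":
                m = _CONSTRAINT_RE.match(line)
                if not m:
                    raise NetworkError(f"bad constraint syntax: {line!r}")
                rxn, coeff, other, const = m.groups()
                constraints.append(
                    (
                        rxn,
                        Fraction(coeff) if coeff else Fraction(0),
                        other,
                        Fraction(const) if const else Fraction(0),
                    )
                )
            elif section == "FREE":
                m = _FREE_RE.match(line)
                if not m:
                    raise NetworkError(f"bad free-flux syntax: {line!r}")
                rxn, kind, lo, hi = m.groups()
                key = f"{rxn}.{kind}"
                if kind == "net":
                    free_net.append(rxn)
                    bounds[key] = (float(lo), float(hi)) if lo else (-np.inf, np.inf)
                else:
                    free_xch.append(rxn)
                    bounds[key] = (float(lo), float(hi)) if lo else (0.0, 0.99)
            else:
                raise NetworkError(f"content outside any section: {line!r}")
        except NetworkError as err:
            raise NetworkError(f"line {lineno}: {err}") from None
        except (ValueError, KeyError) as err:
            raise NetworkError(f"line {lineno}: {err}") from None

    net = AtomTransitionNetwork(
        net_name, metabolites, reactions, constraints, free_net, free_xch, bounds
    )
    for rname, rxn in net.reactions.items():
        if rxn.reversible:
            continue
        # irreversible reactions never carry exchange flux
        if rname in net.free_xch:
            raise NetworkError(f"irreversible reaction {rname} declared free xch")
    for rxn, _, other, _ in constraints:
        for r in (rxn, other):
            if r is not None and r not in net.reactions:
                raise NetworkError(f"constraint references undeclared reaction {r}")
    net.validate()
    return net


def _parse_reaction(line: str) -> Reaction:
    m = _REACTION_RE.match(line)
    if not m:
        raise NetworkError(f"bad reaction syntax: {line!r}")
    rname, lhs, rhs, rev = m.groups()
    reactants = _parse_side(lhs)
    alternatives = tuple(_parse_side(alt) for alt in rhs.split("|"))
    return Reaction(rname, reactants, alternatives, reversible=bool(rev))


def _parse_side(text: str) -> Side:
    if not text.strip():
        # pseudo-reaction side (e.g. a pure bookkeeping flux like biomass)
        return ()
    instances = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise NetworkError("empty term in reaction side")
        m = _INSTANCE_RE.match(term)
        if not m:
            raise NetworkError(f"bad species term: {term!r}")
        met, lbl = m.groups()
        instances.append((met, lbl or ""))
    return tuple(instances)


# ---------------------------------------------------------------------------
# flux algebra

def stoichiometric_matrix(
    net: AtomTransitionNetwork,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Net stoichiometric matrix over internal metabolites.

    Returns (S, row_names, column_names) with S[m, r] the net coefficient of
    internal metabolite m in reaction r.
    """
    rows = net.internal_names()
    cols = net.reaction_order()
    S = np.zeros((len(rows), len(cols)))
    ridx = {m: i for i, m in enumerate(rows)}
    for j, rname in enumerate(cols):
        rxn = net.reactions[rname]
        for met, _ in rxn.reactants:
            if met in ridx:
                S[ridx[met], j] -= 1.0
        for met, _ in rxn.products:
            if met in ridx:
                S[ridx[met], j] += 1.0
    return S, rows, cols


def _exact_stoich(net: AtomTransitionNetwork) -> sympy.Matrix:
    rows = net.internal_names()
    cols = net.reaction_order()
    S = sympy.zeros(len(rows), len(cols))
    ridx = {m: i for i, m in enumerate(rows)}
    for j, rname in enumerate(cols):
        rxn = net.reactions[rname]
        for met, _ in rxn.reactants:
            if met in ridx:
                S[ridx[met], j] -= 1
        for met, _ in rxn.products:
            if met in ridx:
                S[ridx[met], j] += 1
    return S


def free_flux_basis(
    net: AtomTransitionNetwork,
    designated_free: list[str] | None = None,
    constraints: dict[str, float] | None = None,
) -> FreeFluxParameterization:
    """Exact linear parameterization of the steady-state net-flux space.

    ``designated_free`` lists free fluxes as ``"R1.net"`` / ``"R1.xch"``
    (bare names mean ``.net``); defaults to the network's FREE section.
    ``constraints`` adds fixed values on top of the network's CONSTRAINTS
    section.  The combination must determine the null space exactly;
    under- or over-determination raises with the rank deficit.
    """
    if designated_free is None:
        free_net = list(net.free_net)
        free_xch = list(net.free_xch)
    else:
        free_net, free_xch = [], []
        for name in designated_free:
            base, _, kind = name.partition(".")
            if base not in net.reactions:
                raise NetworkError(f"free flux references undeclared reaction {base}")
            if kind == "xch":
                free_xch.append(base)
            else:
                free_net.append(base)

    order = net.reaction_order()
    syms = {r: sympy.Symbol(f"v_{r}") for r in order}
    fsyms = [sympy.Symbol(f"f_{r}") for r in free_net]

    equations = []
    S = _exact_stoich(net)
    vvec = sympy.Matrix([syms[r] for r in order])
    balance = S * vvec
    equations.extend(balance[i, 0] for i in range(balance.rows))
    for rxn, coeff, other, const in net.constraints:
        rhs = sympy.Rational(const)
        if other is not None:
            rhs += sympy.Rational(coeff) * syms[other]
        equations.append(syms[rxn] - rhs)
    for rname, val in (constraints or {}).items():
        base = rname.split(".")[0]
        if base not in net.reactions:
            raise NetworkError(f"constraint references undeclared reaction {base}")
        equations.append(syms[base] - sympy.Rational(str(val)))
    for r, f in zip(free_net, fsyms):
        equations.append(syms[r] - f)

    unknowns = [syms[r] for r in order]
    A, b = sympy.linear_eq_to_matrix(equations, unknowns)
    # b may contain the free-flux symbols; solve A x = b symbolically in f.
    rank_A = A.rank()
    aug = A.row_join(b)
    # treat free symbols as part of the rhs: rank of augmented matrix with
    # symbolic entries is evaluated generically
    rank_aug = aug.rank()
    n = len(unknowns)
    if rank_A < n:
        raise NetworkError(f"underdetermined: rank deficit {n - rank_A}")
    if rank_aug > rank_A:
        raise NetworkError(
            f"overdetermined: {rank_aug - rank_A} independent conflicting constraints"
        )
    solset = sympy.linsolve((A, b), unknowns)
    if not solset:
        raise NetworkError("overdetermined: constraints are inconsistent")
    sol = list(next(iter(solset)))

    basis = np.zeros((n, len(free_net)))
    offset = np.zeros(n)
    for i in range(n):
        expr = sympy.expand(sol[i])
        poly = expr
        const = poly.subs({f: 0 for f in fsyms})
        offset[i] = float(const)
        for j, f in enumerate(fsyms):
            basis[i, j] = float(poly.coeff(f, 1))

    bounds = dict(net.bounds)
    for r in free_xch:
        bounds.setdefault(f"{r}.xch", (0.0, 0.99))
    return FreeFluxParameterization(
        network=net,
        free_net_names=free_net,
        free_xch_names=free_xch,
        reaction_order=order,
        basis=basis,
        offset=offset,
        bounds=bounds,
    )


def complete_fluxes(
    param: FreeFluxParameterization,
    values,
    check_bounds: bool = True,
) -> FluxState:
    """Expand a free-flux vector (net frees then xch frees) to a FluxState."""
    values = np.asarray(values, dtype=float)
    if values.shape != (param.n_free,):
        raise NetworkError(
            f"expected {param.n_free} free-flux values, got {values.shape}"
        )
    if check_bounds:
        lo, hi = param.bounds_arrays()
        bad = (values < lo - 1e-12) | (values > hi + 1e-12)
        if bad.any():
            name = param.free_names[int(np.argmax(bad))]
            raise NetworkError(f"free flux {name} outside its bounds")
    n_net = len(param.free_net_names)
    vnet = param.basis @ values[:n_net] + param.offset
    net = dict(zip(param.reaction_order, vnet))
    xch = dict(zip(param.free_xch_names, values[n_net:]))
    state = FluxState(net=net, xch01=xch)
    state.validate(param.network)
    return state
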