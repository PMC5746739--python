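"""Steady-state isotope-label simulation on atom-transition networks.

Two independent routes are provided:

* an EMU (elementary metabolite unit) cascade — the production code path.
  The minimal set of carbon subsets needed for the requested fragments is
  found by walking atom maps backwards from the targets; the steady-state
  mass-isotopomer distribution (MID) of every EMU of size s solves a linear
  system whose sources are substrate labelling and convolutions of
  smaller-size EMU MIDs.
* a brute-force positional-isotopomer balance solved by fixed-point
  iteration — the validation oracle, restricted to small networks.

Mass-isotopomer vectors sum to one; positional isotopomer distributions are
indexed by binary patterns with ``0`` for 12C and ``1`` for 13C, position 1
first (``"10"`` = carbon 1 labelled, carbon 2 not).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import AtomTransitionNetwork, FluxState, NetworkError

__all__ = [
    "SubstrateLabelling",
    "IsotopomerDistribution",
    "MIDVector",
    "FragmentTarget",
    "EMUSystem",
    "parse_fragment",
    "decompose_emus",
    "simulate_mids",
    "simulate_isotopomers_oracle",
    "simulate_isotopomers_emu",
    "positional_abundances",
    "sweep_toy_network",
]

NATURAL_ABUNDANCE_13C = 0.011

_ZERO_FLUX = 1e-12


# ---------------------------------------------------------------------------
# tracers

@dataclass
class SubstrateLabelling:
    """Isotopomer mixture of the fed substrates.

    ``patterns`` maps each substrate to ``{binary pattern: fraction}``; e.g.
    80% [1-13C] + 20% [13C6] glucose is ``{"Gluc": {"100000": 0.8,
    "111111": 0.2}}``.  Positions marked ``0`` are 13C with probability
    ``natural_abundance`` (0 for pure simulations, 0.011 when emulating
    experiments); positions marked ``1`` are 13C with probability 1.
    """

    patterns: dict[str, dict[str, float]]
    natural_abundance: float = 0.0

    def __post_init__(self):
        for met, pats in self.patterns.items():
            total = sum(pats.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"substrate {met}: fractions sum to {total}, not 1")
            lengths = {len(p) for p in pats}
            if len(lengths) > 1:
                raise ValueError(f"substrate {met}: inconsistent pattern lengths")

    def _carbon_p(self, char: str) -> float:
        return 1.0 if char == "1" else self.natural_abundance

    def emu_mid(self, met: str, carbons: tuple[int, ...]) -> np.ndarray:
        """MID of the given carbon subset (1-based) of a substrate."""
        pats = self.patterns[met]
        out = np.zeros(len(carbons) + 1)
        for pattern, frac in pats.items():
            mid = np.array([1.0])
            for c in carbons:
                p = self._carbon_p(pattern[c - 1])
                mid = np.convolve(mid, [1.0 - p, p])
            out += frac * mid
        return out

    def isotopomer_distribution(self, met: str, n_carbons: int) -> np.ndarray:
        pats = self.patterns[met]
        out = np.zeros(2 ** n_carbons)
        for pattern, frac in pats.items():
            probs = [self._carbon_p(ch) for ch in pattern]
            for idx in range(2 ** n_carbons):
                p = 1.0
                for c in range(n_carbons):
                    p *= probs[c] if (idx >> c) & 1 else 1.0 - probs[c]
                out[idx] += frac * p
        return out


# ---------------------------------------------------------------------------
# result containers

def pattern_index(pattern: str) -> int:
    return sum(1 << i for i, ch in enumerate(pattern) if ch == "1")


def index_pattern(idx: int, n: int) -> str:
    return "".join("1" if (idx >> i) & 1 else "0" for i in range(n))


@dataclass
class IsotopomerDistribution:
    """Positional-isotopomer abundances of one metabolite.

    ``abundances[i]`` is the fraction of molecules with labelling pattern
    ``index_pattern(i, n)``.
    """

    metabolite: str
    abundances: np.ndarray

    @property
    def n_carbons(self) -> int:
        return int(np.log2(len(self.abundances)) + 0.5)

    def __getitem__(self, pattern: str) -> float:
        return float(self.abundances[pattern_index(pattern)])

    def validate(self, tol: float = 1e-9) -> None:
        if (self.abundances < -tol).any():
            raise ValueError(f"{self.metabolite}: negative isotopomer abundance")
        if abs(self.abundances.sum() - 1.0) > tol:
            raise ValueError(f"{self.metabolite}: abundances sum to "
                             f"{self.abundances.sum()}")


@dataclass
class MIDVector:
    """Mass-isotopomer abundances M0..Mn of a fragment of n carbons."""

    fragment_id: str
    abundances: np.ndarray

    @property
    def n_carbons(self) -> int:
        return len(self.abundances) - 1

    def validate(self, tol: float = 1e-9) -> None:
        if abs(self.abundances.sum() - 1.0) > tol:
            raise ValueError(f"{self.fragment_id}: MID sums to "
                             f"{self.abundances.sum()}")
        if (self.abundances < -tol).any():
            raise ValueError(f"{self.fragment_id}: negative noise-free abundance")


@dataclass(frozen=True)
class FragmentTarget:
    """A measurable fragment: the convolution of one or more metabolite EMUs.

    A plain network fragment has a single part; an amino-acid fragment
    assembled from several precursors (e.g. Phe from 2 PEP + E4P) has one
    part per precursor unit.
    """

    id: str
    parts: tuple[tuple[str, tuple[int, ...]], ...]

    @property
    def n_carbons(self) -> int:
        return sum(len(c) for _, c in self.parts)


_FRAG_RE = re.compile(r"^(\w+)(?:\[(\d+)-(\d+)\]|\[([\d,]+)\])?$")


def parse_fragment(spec: str) -> FragmentTarget:
    """Parse ``Met[i-j]`` / ``Met[i,j,k]`` (1-based, inclusive) or ``Met``."""
    m = _FRAG_RE.match(spec.strip())
    if not m:
        raise ValueError(f"bad fragment spec: {spec!r}")
    met, lo, hi, listed = m.groups()
    if lo is not None:
        carbons = tuple(range(int(lo), int(hi) + 1))
    elif listed is not None:
        carbons = tuple(int(x) for x in listed.split(","))
    else:
        carbons = ()
    return FragmentTarget(spec.strip(), ((met, carbons),))


def _resolve_target(net: AtomTransitionNetwork, target) -> FragmentTarget:
    if isinstance(target, FragmentTarget):
        frag = target
    else:
        frag = parse_fragment(target)
    parts = []
    for met, carbons in frag.parts:
        if met not in net.metabolites:
            raise NetworkError(f"fragment {frag.id}: unknown metabolite {met}")
        n = net.metabolites[met].n_carbons
        if not carbons:
            carbons = tuple(range(1, n + 1))
        if any(c < 1 or c > n for c in carbons):
            raise NetworkError(
                f"fragment {frag.id}: carbon index outside 1..{n} of {met}"
            )
        parts.append((met, carbons))
    return FragmentTarget(frag.id, tuple(parts))


# ---------------------------------------------------------------------------
# EMU decomposition

EMUKey = tuple[str, frozenset]


@dataclass
class _Step:
    """One unidirectional atom-map instance of a reaction."""

    reaction: str
    forward: bool
    weight: float  # 1 / number of alternative maps
    reactants: tuple
    products: tuple


@dataclass
class EMUSystem:
    network: AtomTransitionNetwork
    targets: list[FragmentTarget]
    steps: list[_Step]
    unknowns: list[EMUKey]  # ordered by size then discovery
    terms: dict[EMUKey, list[tuple[int, tuple]]]
    # terms[emu] = [(step_idx, sources)], sources a tuple of EMUKey (internal
    # pools) or ("@sub", met, carbons) markers for substrate EMUs

    def sizes(self) -> list[int]:
        return sorted({len(e[1]) for e in self.unknowns})

    def solve(
        self, flux: FluxState, tracer: SubstrateLabelling
    ) -> dict[EMUKey, np.ndarray]:
        """Solve the size-ordered EMU cascade for one flux state."""
        net = self.network
        step_flux = np.empty(len(self.steps))
        for i, st in enumerate(self.steps):
            v = flux.forward(st.reaction) if st.forward else flux.backward(st.reaction)
            step_flux[i] = v * st.weight

        production: dict[str, float] = {m: 0.0 for m in net.metabolites}
        for i, st in enumerate(self.steps):
            for met, _ in st.products:
                production[met] += step_flux[i]

        solved: dict[EMUKey, np.ndarray] = {}

        def source_mid(src) -> np.ndarray | None:
            if src[0] == "@sub":
                return tracer.emu_mid(src[1], src[2])
            return solved.get(src)

        by_size: dict[int, list[EMUKey]] = {}
        for emu in self.unknowns:
            by_size.setdefault(len(emu[1]), []).append(emu)

        for size in sorted(by_size):
            block = by_size[size]
            idx = {emu: i for i, emu in enumerate(block)}
            nb = len(block)
            A = np.zeros((nb, nb))
            B = np.zeros((nb, size + 1))
            pruned = []
            for emu in block:
                i = idx[emu]
                denom = production[emu[0]]
                if denom < _ZERO_FLUX:
                    pruned.append(i)
                    A[i, i] = 1.0
                    B[i, 0] = 1.0  # unlabelled placeholder for a dead pool
                    warnings.warn(
                        f"pool {emu[0]} has ~zero throughput; EMU "
                        f"{sorted(emu[1])} set to unlabelled",
                        stacklevel=2,
                    )
                    continue
                A[i, i] = denom
                for step_idx, sources in self.terms[emu]:
                    v = step_flux[step_idx]
                    if v == 0.0:
                        continue
                    if (
                        len(sources) == 1
                        and sources[0][0] != "@sub"
                        and sources[0] in idx
                        and sources[0] not in solved
                    ):
                        A[i, idx[sources[0]]] -= v
                        continue
                    mid = np.array([1.0])
                    for src in sources:
                        part = source_mid(src)
                        if part is None:
                            raise NetworkError(
                                f"EMU cascade ordering broken at {emu}"
                            )
                        mid = np.convolve(mid, part)
                    B[i, :] += v * mid
            try:
                X = np.linalg.solve(A, B)
            except np.linalg.LinAlgError as err:
                raise NetworkError(f"singular EMU system at size {size}: {err}")
            for emu in block:
                solved[emu] = X[idx[emu]]
        return solved

    def fragment_mids(
        self, flux: FluxState, tracer: SubstrateLabelling
    ) -> list[MIDVector]:
        solved = self.solve(flux, tracer)
        out = []
        for frag in self.targets:
            mid = np.array([1.0])
            for met, carbons in frag.parts:
                key = (met, frozenset(carbons))
                if self.network.metabolites[met].role == "substrate":
                    part = tracer.emu_mid(met, carbons)
                else:
                    part = solved[key]
                mid = np.convolve(mid, part)
            out.append(MIDVector(frag.id, mid))
        return out


def _unidirectional_steps(net: AtomTransitionNetwork) -> list[_Step]:
    steps = []
    for rxn in net.reactions.values():
        w = 1.0 / len(rxn.product_alternatives)
        for alt in rxn.product_alternatives:
            steps.append(_Step(rxn.name, True, w, rxn.reactants, alt))
            if rxn.reversible:
                steps.append(_Step(rxn.name, False, w, alt, rxn.reactants))
    return steps


def decompose_emus(net: AtomTransitionNetwork, targets) -> EMUSystem:
    """Build the minimal EMU system sufficient for the requested fragments."""
    frags = [_resolve_target(net, t) for t in targets]
    steps = _unidirectional_steps(net)

    needed: list[EMUKey] = []
    for frag in frags:
        for met, carbons in frag.parts:
            if net.metabolites[met].role != "substrate":
                needed.append((met, frozenset(carbons)))

    terms: dict[EMUKey, list[tuple[int, tuple]]] = {}
    order: list[EMUKey] = []
    stack = list(dict.fromkeys(needed))
    seen = set(stack)
    while stack:
        emu = stack.pop()
        order.append(emu)
        met, carbons = emu
        emu_terms: list[tuple[int, tuple]] = []
        for step_idx, st in enumerate(steps):
            for pmet, plbl in st.products:
                if pmet != met:
                    continue
                wanted = {plbl[c - 1] for c in carbons}
                sources = []
                for rmet, rlbl in st.reactants:
                    sub = tuple(
                        pos + 1 for pos, ch in enumerate(rlbl) if ch in wanted
                    )
                    if sub:
                        sources.append((rmet, sub))
                if not sources:
                    continue
                refs = []
                for rmet, sub in sources:
                    if net.metabolites[rmet].role == "substrate":
                        refs.append(("@sub", rmet, sub))
                    else:
                        key = (rmet, frozenset(sub))
                        refs.append(key)
                        if key not in seen:
                            seen.add(key)
                            stack.append(key)
                emu_terms.append((step_idx, tuple(refs)))
        if not emu_terms:
            raise NetworkError(
                f"fragment EMU {met}{sorted(carbons)} is unreachable from any substrate"
            )
        terms[emu] = emu_terms

    # every EMU must ground out in substrate labelling: a pool fed only by an
    # isolated cycle can never acquire a defined composition
    grounded: set[EMUKey] = set()
    changed = True
    while changed:
        changed = False
        for emu, emu_terms in terms.items():
            if emu in grounded:
                continue
            for _, refs in emu_terms:
                if all(r[0] == "@sub" or r in grounded for r in refs):
                    grounded.add(emu)
                    changed = True
                    break
    ungrounded = [e for e in terms if e not in grounded]
    if ungrounded:
        met, carbons = ungrounded[0]
        raise NetworkError(
            f"fragment EMU {met}{sorted(carbons)} is unreachable from any substrate"
        )

    order.sort(key=lambda e: len(e[1]))
    return EMUSystem(net, frags, steps, order, terms)


def simulate_mids(
    net: AtomTransitionNetwork,
    flux: FluxState,
    tracer: SubstrateLabelling,
    targets,
    system: EMUSystem | None = None,
) -> list[MIDVector]:
    """Steady-state MIDs of the requested fragments under one flux state.

    Pass a pre-built ``system`` (from :func:`decompose_emus`) when calling
    repeatedly with different flux values.
    """
    if system is None:
        system = decompose_emus(net, targets)
    return system.fragment_mids(flux, tracer)


# ---------------------------------------------------------------------------
# brute-force oracle

def simulate_isotopomers_oracle(
    net: AtomTransitionNetwork,
    flux: FluxState,
    tracer: SubstrateLabelling,
    metabolites: list[str],
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> list[IsotopomerDistribution]:
    """Full positional-isotopomer balance by fixed-point iteration.

    Independent of the EMU route: every non-substrate pool's complete
    2^n-vector is iterated until the flux-weighted inflow matches the pool
    composition.  Limited to networks with at most 16 total carbons over the
    iterated pools.
    """
    pools = [
        m.name
        for m in net.metabolites.values()
        if m.role != "substrate" and m.n_carbons > 0
    ]
    total_c = sum(net.metabolites[m].n_carbons for m in pools)
    if total_c > 16:
        raise NetworkError(
            f"oracle size limit exceeded: {total_c} carbons over iterated pools"
        )

    steps = _unidirectional_steps(net)
    step_flux = []
    for st in steps:
        v = flux.forward(st.reaction) if st.forward else flux.backward(st.reaction)
        step_flux.append(v * st.weight)

    production = {m: 0.0 for m in net.metabolites}
    for v, st in zip(step_flux, steps):
        for met, _ in st.products:
            production[met] += v

    dist: dict[str, np.ndarray] = {}
    for m in net.metabolites.values():
        if m.role == "substrate":
            dist[m.name] = tracer.isotopomer_distribution(m.name, m.n_carbons)
        elif m.n_carbons > 0:
            d = np.zeros(2 ** m.n_carbons)
            d[0] = 1.0
            dist[m.name] = d

    # precompute, per step, the product-pattern map for each joint reactant
    # pattern (label characters carried from reactant carbons to products)
    compiled = []
    for st in steps:
        r_mets = [met for met, _ in st.reactants]
        r_sizes = [len(lbl) for _, lbl in st.reactants]
        maps = []
        for combo in itertools.product(*[range(2 ** s) for s in r_sizes]):
            labelled = set()
            for (rmet, rlbl), bits in zip(st.reactants, combo):
                for pos, ch in enumerate(rlbl):
                    if (bits >> pos) & 1:
                        labelled.add(ch)
            prods = []
            for pmet, plbl in st.products:
                pidx = 0
                for pos, ch in enumerate(plbl):
                    if ch in labelled:
                        pidx |= 1 << pos
                prods.append((pmet, pidx))
            maps.append((combo, prods))
        compiled.append((r_mets, maps))

    live = [m for m in pools if production[m] > _ZERO_FLUX]
    for m in pools:
        if production[m] <= _ZERO_FLUX:
            warnings.warn(f"pool {m} has ~zero throughput; left unlabelled",
                          stacklevel=2)

    def inflows():
        acc = {m: np.zeros_like(dist[m]) for m in live}
        for v, (r_mets, maps) in zip(step_flux, compiled):
            if v == 0.0:
                continue
            for combo, prods in maps:
                p = v
                for rmet, bits in zip(r_mets, combo):
                    p *= dist[rmet][bits]
                    if p == 0.0:
                        break
                if p == 0.0:
                    continue
                for pmet, pidx in prods:
                    if pmet in acc:
                        acc[pmet][pidx] += p
        return acc

    # The balance is bilinear in the unknown distributions (condensation
    # reactions), and the raw functional iteration loses probability mass
    # when exchange fluxes are large.  Renormalizing each pool every sweep
    # keeps the iterate on the simplex, where the map contracts; the final
    # residual check below guards against converging to anything that does
    # not satisfy the un-normalized balances.
    for _ in range(max_iter):
        inflow = inflows()
        delta = 0.0
        for m in live:
            new = inflow[m] / production[m]
            total = new.sum()
            if total > 0:
                new = new / total
            delta = max(delta, float(np.abs(new - dist[m]).max()))
            dist[m] = new
        if delta < tol:
            break
    else:
        raise NetworkError(f"oracle did not converge in {max_iter} iterations")

    inflow = inflows()
    for m in live:
        resid = np.abs(inflow[m] / production[m] - dist[m]).max()
        if resid > 1e4 * tol:
            raise NetworkError(
                f"oracle converged to an unbalanced state at {m} "
                f"(residual {resid:.2e})"
            )

    return [IsotopomerDistribution(m, dist[m]) for m in metabolites]


def simulate_isotopomers_emu(
    net: AtomTransitionNetwork,
    flux: FluxState,
    tracer: SubstrateLabelling,
    metabolites: list[str],
    system: EMUSystem | None = None,
) -> list[IsotopomerDistribution]:
    """Positional isotopomer distributions via the EMU route.

    The top mass of each carbon-subset EMU is the cumulative (cumomer)
    fraction P(all carbons in the subset labelled); Moebius inversion over
    the subset lattice recovers the isotopomer distribution.  Needs all
    2^n - 1 EMUs of each metabolite, so intended for small pools (n <= 12).
    """
    if system is None:
        targets = []
        for m in metabolites:
            n = net.metabolites[m].n_carbons
            if n > 12:
                raise NetworkError(f"{m}: too many carbons for full inversion")
            for mask in range(1, 2 ** n):
                carbons = tuple(c + 1 for c in range(n) if (mask >> c) & 1)
                targets.append(FragmentTarget(f"{m}#{mask}", ((m, carbons),)))
        system = decompose_emus(net, targets)
    solved = system.solve(flux, tracer)

    out = []
    for m in metabolites:
        n = net.metabolites[m].n_carbons
        gamma = np.empty(2 ** n)
        gamma[0] = 1.0
        for mask in range(1, 2 ** n):
            carbons = frozenset(c + 1 for c in range(n) if (mask >> c) & 1)
            if net.metabolites[m].role == "substrate":
                mid = tracer.emu_mid(m, tuple(sorted(carbons)))
            else:
                mid = solved[(m, carbons)]
            gamma[mask] = mid[-1]
        x = np.empty(2 ** n)
        full = 2 ** n - 1
        for mask in range(2 ** n):
            rest = full & ~mask
            acc = 0.0
            sub = rest
            while True:
                t = mask | sub
                acc += ((-1) ** bin(sub).count("1")) * gamma[t]
                if sub == 0:
                    break
                sub = (sub - 1) & rest
            x[mask] = acc
        out.append(IsotopomerDistribution(m, x))
    return out


def positional_abundances(dist: IsotopomerDistribution) -> np.ndarray:
    """Marginal 13C fraction at each carbon position."""
    n = dist.n_carbons
    out = np.zeros(n)
    for idx, a in enumerate(dist.abundances):
        for c in range(n):
            if (idx >> c) & 1:
                out[c] += a
    return out


def sweep_toy_network(
    net: AtomTransitionNetwork,
    grid: dict[str, np.ndarray],
    tracer: SubstrateLabelling,
    metabolites: list[str] | None = None,
) -> list[dict]:
    """Isotopomer datasets over a grid of free-flux values.

    ``grid`` maps free-flux names (as in the network's FREE section) to value
    arrays; the sweep covers their Cartesian product.  Each record holds the
    free values and the positional-isotopomer distribution of every requested
    (default: every internal) metabolite.
    """
    from .network import complete_fluxes, free_flux_basis

    param = free_flux_basis(net)
    if metabolites is None:
        metabolites = net.internal_names()
    names = param.free_names
    for g in grid:
        if g not in names:
            raise NetworkError(f"{g} is not a free flux of {net.name}")
    axes = [np.atleast_1d(np.asarray(grid.get(n, [0.0]))) for n in names]
    records = []
    for values in itertools.product(*axes):
        flux = complete_fluxes(param, np.array(values))
        dists = simulate_isotopomers_emu(net, flux, tracer, metabolites)
        records.append(
            {
                "free": dict(zip(names, map(float, values))),
                "distributions": {d.metabolite: d for d in dists},
            }
        )
    return records
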