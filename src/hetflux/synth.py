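"""Generators for every input the pipeline consumes.

Ships the two toy networks (a single-variable-flux branch and its variant
with a reversible branch reaction), a canonical uncompartmented network of
core carbon metabolism (glycolysis, oxidative PPP, TCA, glyoxylate cycle,
PEPCase, malic enzyme, biomass drains), the default panel of 27 tBDMS
amino-acid fragments from 12 proteinogenic amino acids with their precursor
carbon maps, an ion-count-dependent GC-MS noise model, and paired null
datasets for reporter-vs-total-protein equivalence testing.

The canonical atom maps follow standard E. coli core biochemistry; biomass
drain coefficients are Neidhardt-style precursor demands (mmol per unit
biomass flux).  These reconstructions are synthetic stand-ins for the
original study's unpublished model definitions and are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .midtools import FragmentSpec, MeasurementSet
from .network import (
    AtomTransitionNetwork,
    FreeFluxParameterization,
    complete_fluxes,
    free_flux_basis,
    parse_network,
)
from .simulate import FragmentTarget, SubstrateLabelling

__all__ = [
    "FIG1_TEXT",
    "FIG2_TEXT",
    "CANONICAL_TEXT",
    "TABLE1_FREE_FLUXES",
    "NoiseModel",
    "build_fig1_network",
    "build_fig2_network",
    "build_canonical_network",
    "toy_tracer",
    "glucose_tracer",
    "default_fragment_panel",
    "panel_targets",
    "generate_gcms_noise",
    "generate_reporter_null_dataset",
    "random_feasible_states",
]

FIG1_TEXT = """\
# Branch-point toy network: substrate S feeds intermediate A, whose carbons
# reach products B and C by two alternative irreversible routes.
NETWORK fig1
METABOLITES
S 2 substrate
A 2 internal
B 1 sink
C 1 sink
REACTIONS
R0: S (ab) -> A (ab)
R1: A (ab) -> B (a) + C (b)
R2: A (ab) -> B (b) + C (a)
CONSTRAINTS
R0.net = 1
FREE
R1.net in [0, 1]
"""

FIG2_TEXT = """\
# Same branch-point network with R1 reversible (condensation B + C -> A),
# so the flux space has one net and one exchange degree of freedom.
NETWORK fig2
METABOLITES
S 2 substrate
A 2 internal
B 1 internal
C 1 internal
Bout 1 sink
Cout 1 sink
REACTIONS
R0: S (ab) -> A (ab)
R1: A (ab) -> B (a) + C (b) rev
R2: A (ab) -> B (b) + C (a)
R3: B (a) -> Bout (a)
R4: C (a) -> Cout (a)
CONSTRAINTS
R0.net = 1
FREE
R1.net in [0, 1]
R1.xch in [0, 0.99]
"""

# Uncompartmented core carbon metabolism: EMP glycolysis, oxidative PPP
# (G6PDH + 6PGDH lumped), non-oxidative PPP with canonical TK/TA carbon
# maps, full TCA with succinate/fumarate scrambling, glyoxylate bypass,
# PEP carboxylase, malic enzyme, CO2 pool recycled through PEPCase, and
# biomass drains from ten precursors tied to one biomass flux.
CANONICAL_TEXT = """\
NETWORK canonical
METABOLITES
Gluc 6 substrate
G6P 6 internal
F6P 6 internal
GAP 3 internal
PGA 3 internal
PEP 3 internal
PYR 3 internal
AcCoA 2 internal
Ru5P 5 internal
R5P 5 internal
X5P 5 internal
S7P 7 internal
E4P 4 internal
ICT 6 internal
AKG 5 internal
SUC 4 internal
FUM 4 internal
MAL 4 internal
OAA 4 internal
GLX 2 internal
CO2 1 internal
CO2out 1 sink
BMG6P 6 sink
BMF6P 6 sink
BMR5P 5 sink
BME4P 4 sink
BMPGA 3 sink
BMPEP 3 sink
BMPYR 3 sink
BMAC 2 sink
BMAKG 5 sink
BMOAA 4 sink
REACTIONS
v_upt: Gluc (abcdef) -> G6P (abcdef)
v_pgi: G6P (abcdef) -> F6P (abcdef) rev
v_pfk: F6P (abcdef) -> GAP (cba) + GAP (def)
v_gap: GAP (abc) -> PGA (abc)
v_eno: PGA (abc) -> PEP (abc)
v_pyk: PEP (abc) -> PYR (abc)
v_pdh: PYR (abc) -> AcCoA (bc) + CO2 (a)
v_g6pdh: G6P (abcdef) -> Ru5P (bcdef) + CO2 (a)
v_rpi: Ru5P (abcde) -> R5P (abcde) rev
v_rpe: Ru5P (abcde) -> X5P (abcde) rev
v_tk1: X5P (abcde) + R5P (fghij) -> S7P (abfghij) + GAP (cde) rev
v_tk2: X5P (abcde) + E4P (fghi) -> F6P (abfghi) + GAP (cde) rev
v_ta: S7P (abcdefg) + GAP (hij) -> E4P (defg) + F6P (abchij) rev
v_cs: OAA (abcd) + AcCoA (ef) -> ICT (abcdef)
v_icdh: ICT (abcdef) -> AKG (dcbfe) + CO2 (a)
v_icl: ICT (abcdef) -> SUC (abfe) + GLX (cd)
v_ms: GLX (ab) + AcCoA (cd) -> MAL (badc)
v_akgdh: AKG (abcde) -> SUC (bcde) + CO2 (a)
v_sdh: SUC (abcd) -> FUM (abcd) | FUM (dcba) rev
v_fum: FUM (abcd) -> MAL (abcd) | MAL (dcba) rev
v_mdh: MAL (abcd) -> OAA (abcd)
v_ppc: PEP (abc) + CO2 (d) -> OAA (abcd)
v_mae: MAL (abcd) -> PYR (abc) + CO2 (d)
v_co2x: CO2 (a) -> CO2out (a)
v_bm: ->
v_bm_g6p: G6P (abcdef) -> BMG6P (abcdef)
v_bm_f6p: F6P (abcdef) -> BMF6P (abcdef)
v_bm_r5p: R5P (abcde) -> BMR5P (abcde)
v_bm_e4p: E4P (abcd) -> BME4P (abcd)
v_bm_pga: PGA (abc) -> BMPGA (abc)
v_bm_pep: PEP (abc) -> BMPEP (abc)
v_bm_pyr: PYR (abc) -> BMPYR (abc)
v_bm_ac: AcCoA (ab) -> BMAC (ab)
v_bm_akg: AKG (abcde) -> BMAKG (abcde)
v_bm_oaa: OAA (abcd) -> BMOAA (abcd)
COFACTORS
v_gap: NADH +1
v_pdh: NADH +1
v_icdh: NADPH +1
v_akgdh: NADH +1
v_mdh: NADH +1
v_sdh: FADH2 +1
v_g6pdh: NADPH +2
v_mae: NADPH +1
CONSTRAINTS
v_bm_g6p.net = 0.205 * v_bm.net
v_bm_f6p.net = 0.071 * v_bm.net
v_bm_r5p.net = 0.898 * v_bm.net
v_bm_e4p.net = 0.361 * v_bm.net
v_bm_pga.net = 1.496 * v_bm.net
v_bm_pep.net = 0.519 * v_bm.net
v_bm_pyr.net = 2.833 * v_bm.net
v_bm_ac.net = 3.748 * v_bm.net
v_bm_akg.net = 1.079 * v_bm.net
v_bm_oaa.net = 1.787 * v_bm.net
FREE
v_upt.net in [1, 1000]
v_bm.net in [0.1, 20]
v_g6pdh.net in [0, 500]
v_ppc.net in [0, 500]
v_icl.net in [0, 200]
"""

#: reference flux state of the canonical network (glucose uptake, biomass,
#: G6PDH, PEPCase, ICL) used throughout the mixture experiments
TABLE1_FREE_FLUXES = {
    "v_upt.net": 100.0,
    "v_bm.net": 7.56,
    "v_g6pdh.net": 50.0,
    "v_ppc.net": 80.0,
    "v_icl.net": 25.0,
}


def build_fig1_network() -> AtomTransitionNetwork:
    return parse_network(FIG1_TEXT)


def build_fig2_network() -> AtomTransitionNetwork:
    return parse_network(FIG2_TEXT)


def build_canonical_network() -> AtomTransitionNetwork:
    return parse_network(CANONICAL_TEXT)


def toy_tracer(natural_abundance: float = 0.0) -> SubstrateLabelling:
    """Substrate labelled exclusively in position 1."""
    return SubstrateLabelling({"S": {"10": 1.0}}, natural_abundance)


def glucose_tracer(
    u13c: float = 0.2,
    c1: float = 0.0,
    natural_abundance: float = 0.0,
) -> SubstrateLabelling:
    """Glucose feed: fractions of [13C6] and [1-13C], remainder unlabelled."""
    rest = 1.0 - u13c - c1
    if rest < -1e-12:
        raise ValueError("tracer fractions exceed 1")
    pats = {}
    if u13c:
        pats["111111"] = u13c
    if c1:
        pats["100000"] = c1
    if rest > 1e-15:
        pats["000000"] = rest
    return SubstrateLabelling({"Gluc": pats}, natural_abundance)


# ---------------------------------------------------------------------------
# amino-acid fragment panel

# formula (C, H, N, O, S), and the number of tBDMS groups the standard
# derivative carries (alpha-amino + carboxyl, plus side-chain OH/COOH)
_AA_DATA = {
    "Ala": ((3, 7, 1, 2, 0), 2),
    "Gly": ((2, 5, 1, 2, 0), 2),
    "Ser": ((3, 7, 1, 3, 0), 3),
    "Asp": ((4, 7, 1, 4, 0), 3),
    "Thr": ((4, 9, 1, 3, 0), 3),
    "Glu": ((5, 9, 1, 4, 0), 3),
    "Pro": ((5, 9, 1, 2, 0), 2),
    "Phe": ((9, 11, 1, 2, 0), 2),
    "Tyr": ((9, 11, 1, 3, 0), 3),
    "Val": ((5, 11, 1, 2, 0), 2),
    "Leu": ((6, 13, 1, 2, 0), 2),
    "Ile": ((6, 13, 1, 2, 0), 2),
}

# amino-acid backbone carbon -> biosynthetic precursor carbon.  Each entry is
# a list of precursor units; separate units of the same metabolite come from
# independent molecules and convolve.  (aa_positions, metabolite,
# met_positions) are parallel tuples.
_AA_PRECURSORS: dict[str, list[tuple[str, tuple[int, ...], tuple[int, ...]]]] = {
    "Ala": [("PYR", (1, 2, 3), (1, 2, 3))],
    "Gly": [("PGA", (1, 2), (1, 2))],
    "Ser": [("PGA", (1, 2, 3), (1, 2, 3))],
    "Asp": [("OAA", (1, 2, 3, 4), (1, 2, 3, 4))],
    "Thr": [("OAA", (1, 2, 3, 4), (1, 2, 3, 4))],
    "Glu": [("AKG", (1, 2, 3, 4, 5), (1, 2, 3, 4, 5))],
    "Pro": [("AKG", (1, 2, 3, 4, 5), (1, 2, 3, 4, 5))],
    "Phe": [
        ("PEP", (1, 2, 3), (1, 2, 3)),
        ("PEP", (4, 9), (2, 3)),
        ("E4P", (5, 6, 7, 8), (1, 2, 3, 4)),
    ],
    "Tyr": [
        ("PEP", (1, 2, 3), (1, 2, 3)),
        ("PEP", (4, 9), (2, 3)),
        ("E4P", (5, 6, 7, 8), (1, 2, 3, 4)),
    ],
    "Val": [("PYR", (1, 2, 4), (1, 2, 3)), ("PYR", (3, 5), (2, 3))],
    "Leu": [
        ("AcCoA", (1, 2), (1, 2)),
        ("PYR", (3, 5), (2, 3)),
        ("PYR", (4, 6), (2, 3)),
    ],
    "Ile": [("OAA", (1, 2, 4, 5), (1, 2, 3, 4)), ("PYR", (3, 6), (2, 3))],
}

_F302_AAS = ("Ala", "Ser", "Asp")


def _composition_m57(aa: str) -> dict[str, int]:
    (c, h, n, o, s), d = _AA_DATA[aa]
    comp = {"C": 6 * d - 4, "H": h + 14 * d - 9, "N": n, "O": o, "Si": d}
    if s:
        comp["S"] = s
    return comp


def _composition_m159(aa: str) -> dict[str, int]:
    (c, h, n, o, s), d = _AA_DATA[aa]
    comp = {"C": 6 * d - 6, "H": h + 14 * d - 15, "N": n, "O": o - 2, "Si": d - 1}
    if s:
        comp["S"] = s
    return comp


# common low-mass ion retaining backbone C1-C2 with both alpha substituents;
# composition is a documented reconstruction shared by all amino acids
_F302_COMPOSITION = {"C": 12, "H": 30, "N": 1, "O": 2, "Si": 2}


def default_fragment_panel() -> list[FragmentSpec]:
    """27 tBDMS fragments from 12 proteinogenic amino acids.

    [M-57] retains all backbone carbons, [M-159] loses carbon 1, and the
    m/z-302 ion covers carbons 1-2 (included for Ala, Ser, Asp).
    """
    panel = []
    for aa, ((c, *_), _d) in _AA_DATA.items():
        panel.append(
            FragmentSpec(f"{aa}_M-57", aa, tuple(range(1, c + 1)), _composition_m57(aa))
        )
        panel.append(
            FragmentSpec(f"{aa}_M-159", aa, tuple(range(2, c + 1)), _composition_m159(aa))
        )
    for aa in _F302_AAS:
        panel.append(FragmentSpec(f"{aa}_f302", aa, (1, 2), dict(_F302_COMPOSITION)))
    return panel


def panel_targets(panel: list[FragmentSpec] | None = None) -> dict[str, FragmentTarget]:
    """Map each panel fragment to the precursor EMUs whose convolution is its MID."""
    if panel is None:
        panel = default_fragment_panel()
    out = {}
    for frag in panel:
        units = _AA_PRECURSORS[frag.amino_acid]
        parts = []
        for met, aa_pos, met_pos in units:
            picked = tuple(
                mp for ap, mp in zip(aa_pos, met_pos) if ap in frag.backbone_carbons
            )
            if picked:
                parts.append((met, tuple(sorted(picked))))
        out[frag.id] = FragmentTarget(frag.id, tuple(parts))
    return out


# ---------------------------------------------------------------------------
# noise models

@dataclass
class NoiseModel:
    """Ion-count-dependent GC-MS abundance noise.

    Abundance SD is ``a / sqrt(ion_count) + b``: counting statistics plus a
    floor.  Additive Gaussian noise emulates the statistical effect of
    baseline correction, which admits negative abundances for weak signals.
    The model is mean-unbiased and says nothing about chromatography; it
    reproduces the empirical reliability threshold near 1e5 counts.
    """

    a: float = 3.0
    b: float = 1e-4
    seed: int | None = None

    def sd(self, ion_count) -> np.ndarray:
        ion_count = np.asarray(ion_count, dtype=float)
        if (ion_count <= 0).any():
            raise ValueError("ion counts must be positive")
        return self.a / np.sqrt(ion_count) + self.b


def generate_gcms_noise(
    truth: MeasurementSet,
    noise: NoiseModel,
    ion_counts,
) -> MeasurementSet:
    """Noisy realization of a measurement set at the given ion counts.

    ``ion_counts`` is a scalar, a per-row array, or a dict fragment_id ->
    count.  The noisy abundances are not renormalized, mirroring
    independently baseline-corrected mass traces.
    """
    rng = np.random.default_rng(noise.seed)
    out = truth.copy()
    if isinstance(ion_counts, dict):
        counts = out.df["fragment_id"].map(ion_counts).to_numpy(dtype=float)
    else:
        counts = np.broadcast_to(np.asarray(ion_counts, dtype=float), (len(out.df),))
    sd = noise.sd(counts)
    out.df["value"] = out.df["value"].to_numpy() + rng.normal(0.0, sd)
    out.df["sd"] = sd
    out.df["ion_count"] = counts
    return out


def generate_reporter_null_dataset(
    truth: MeasurementSet, sd: float = 0.001, seed: int | None = None
) -> tuple[MeasurementSet, MeasurementSet]:
    """Two independent noisy realizations of one truth.

    The null model under which a purified reporter protein and the total
    protein fraction sample identical amino-acid labelling.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(2):
        s = truth.copy()
        s.df["value"] = s.df["value"].to_numpy() + rng.normal(0.0, sd, len(s.df))
        s.df["sd"] = max(sd, 1e-12)
        sets.append(s)
    return sets[0], sets[1]


def random_feasible_states(
    param: FreeFluxParameterization,
    n: int,
    rng: np.random.Generator,
    box: dict[str, tuple[float, float]] | None = None,
    max_tries: int = 10_000,
):
    """Rejection-sample flux states that satisfy every network invariant."""
    names = param.free_names
    lo, hi = param.bounds_arrays()
    if box:
        for i, name in enumerate(names):
            if name in box:
                lo[i], hi[i] = box[name]
    states = []
    for _ in range(max_tries):
        if len(states) >= n:
            break
        values = rng.uniform(lo, hi)
        try:
            states.append((values, complete_fluxes(param, values)))
        except Exception:
            continue
    if len(states) < n:
        raise RuntimeError(f"only {len(states)} feasible states in {max_tries} tries")
    return states
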