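"""Mixtures of metabolically distinct cell types and what fitting them does.

The central question: if a tissue contains cell types with different flux
distributions, the measured labelling is the weighted average of the
cell-type labelling patterns — does fitting a single network to that
averaged data recover the weighted-average fluxes?  With one variable flux
it does (labelling is linear in the flux); with two or more it generally
does not, because isotopomer abundances are non-linear in the fluxes.

Also provides the reporter-protein equivalence test: regression plus paired
t-test of two measurement sets under the null that a purified cell-type
reporter protein and total protein sample the same amino-acid labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    CISettings,
    FitSettings,
    FluxFitResult,
    MonteCarloSettings,
    Objective,
    continuation_ci,
    fit_fluxes,
    monte_carlo_fit,
)
from .midtools import MeasurementSet, average_measurement_sets
from .network import (
    AtomTransitionNetwork,
    FluxState,
    FreeFluxParameterization,
    complete_fluxes,
)
from .simulate import SubstrateLabelling, simulate_isotopomers_emu, simulate_mids

__all__ = [
    "MixtureScenario",
    "PhysiologySummary",
    "ComparisonReport",
    "weighted_average_flux",
    "simulate_mixture_dataset",
    "run_mixture_experiment",
    "physiology_summary",
    "reporter_equivalence_test",
    "make_balanced_scenario",
]


@dataclass
class MixtureScenario:
    """Cell types sharing one network but supporting different flux states.

    Weights are each cell type's fractional contribution to the measured
    (protein) pool.
    """

    members: list[tuple[FluxState, float]]
    label: str = ""

    def __post_init__(self):
        w = np.array([wt for _, wt in self.members], dtype=float)
        if (w <= 0).any():
            raise ValueError("mixture weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w.sum()}, not 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([wt for _, wt in self.members])


def weighted_average_flux(sc: MixtureScenario) -> FluxState:
    """Per-reaction weighted mean of the member net fluxes.

    Stoichiometric balance is linear, so the average of balanced states is
    balanced.  Exchange fluxes are averaged on the raw (unbounded) scale and
    recompactified.
    """
    first = sc.members[0][0]
    net = {r: 0.0 for r in first.net}
    xch_raw: dict[str, float] = {}
    for state, w in sc.members:
        for r, v in state.net.items():
            net[r] += w * v
        for r in state.xch01:
            xch_raw[r] = xch_raw.get(r, 0.0) + w * state.exchange_raw(r)
    xch01 = {r: e / (1.0 + e) for r, e in xch_raw.items()}
    return FluxState(net=net, xch01=xch01)


def simulate_mixture_dataset(
    net: AtomTransitionNetwork,
    sc: MixtureScenario,
    tracer: SubstrateLabelling,
    targets,
    kind: str = "mid",
    sd: float = 0.001,
    flux_measurements: list[str] | None = None,
) -> MeasurementSet:
    """Weighted average of the member labelling datasets.

    This is the dataset a bulk measurement of the mixed system would yield:
    per-fragment abundances are averaged, not the fluxes.  Reactions listed
    in ``flux_measurements`` contribute direct rate rows (each member's own
    rate, so the average is the true aggregate rate); mass-isotopomer data
    alone pins only flux ratios.
    """
    member_sets = []
    if kind == "mid":
        if isinstance(targets, dict):
            target_map = targets
        else:
            from .simulate import _resolve_target

            resolved = [_resolve_target(net, t) for t in targets]
            target_map = {t.id: t for t in resolved}
    for state, _ in sc.members:
        if kind == "mid":
            mids = simulate_mids(net, state, tracer, list(target_map.values()))
            ms = MeasurementSet.from_mids(mids, targets=target_map, sd=sd)
        elif kind == "isotopomer":
            dists = simulate_isotopomers_emu(net, state, tracer, list(targets))
            ms = MeasurementSet.from_isotopomers(dists, sd=sd)
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
        if flux_measurements:
            ms = ms.with_flux_measurements(
                {r: state.net[r] for r in flux_measurements}
            )
        member_sets.append(ms)
    return average_measurement_sets(member_sets, sc.weights)


@dataclass
class PhysiologySummary:
    """Aggregate gas-exchange and carbon-balance quantities of a flux state."""

    co2_production: float
    o2_uptake: float
    carbons_imported: float
    biomass_output: float | None = None

    @property
    def respiratory_quotient(self) -> float | None:
        if self.o2_uptake > 0:
            return self.co2_production / self.o2_uptake
        return None

    @property
    def carbon_conversion_efficiency(self) -> float | None:
        if self.carbons_imported > 0:
            return 1.0 - self.co2_production / self.carbons_imported
        return None


def physiology_summary(
    net: AtomTransitionNetwork,
    flux: FluxState,
    co2_sink: str = "CO2out",
    biomass_flux: str = "v_bm",
) -> PhysiologySummary:
    """Physiological outputs implied by a flux state.

    CO2 production is the net efflux into the CO2 sink; O2 uptake assumes
    every NADH and FADH2 produced is oxidized by the respiratory chain
    (half a mole of O2 each) while NADPH is consumed by biosynthesis;
    carbon conversion efficiency is the fraction of imported carbon not
    lost as CO2.
    """
    co2 = 0.0
    o2_e = 0.0
    carbons_in = 0.0
    for rname, rxn in net.reactions.items():
        v = flux.net[rname]
        for met, _ in rxn.products:
            if met == co2_sink:
                co2 += v
            if net.metabolites[met].role == "substrate":
                carbons_in -= v * net.metabolites[met].n_carbons
        for met, _ in rxn.reactants:
            if met == co2_sink:
                co2 -= v
            if net.metabolites[met].role == "substrate":
                carbons_in += v * net.metabolites[met].n_carbons
        for species, count in rxn.cofactors.items():
            if species in ("NADH", "FADH2"):
                o2_e += v * float(count)
    biomass = flux.net.get(biomass_flux)
    return PhysiologySummary(
        co2_production=co2,
        o2_uptake=o2_e / 2.0,
        carbons_imported=carbons_in,
        biomass_output=biomass,
    )


@dataclass
class ComparisonReport:
    """Estimated-vs-expected table for a mixture experiment."""

    scenario: str
    table: pd.DataFrame  # columns: quantity, expected, estimate, ci_lo, ci_hi, percent
    fit: FluxFitResult | None = None

    def to_tsv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g")

    def row(self, quantity: str) -> pd.Series:
        sub = self.table[self.table["quantity"] == quantity]
        if sub.empty:
            raise KeyError(quantity)
        return sub.iloc[0]


def _percent(est: float, expected: float) -> float:
    return 100.0 * est / expected if expected != 0 else float("nan")


def run_mixture_experiment(
    net: AtomTransitionNetwork,
    param: FreeFluxParameterization,
    sc: MixtureScenario,
    tracer: SubstrateLabelling,
    targets,
    kind: str = "mid",
    fit_settings: FitSettings | None = None,
    mc: MonteCarloSettings | None = None,
    ci: CISettings | None = None,
    with_physiology: bool | None = None,
    flux_measurements: list[str] | None = None,
) -> ComparisonReport:
    """Fit one aggregate network to averaged mixture labelling data.

    Simulates each member, averages the datasets by mixture weight, assigns
    the nominal sd rule, fits the free fluxes (optionally with Monte Carlo
    replicates and continuation CIs), and tabulates estimates against the
    true weighted-average fluxes.
    """
    mc_settings = mc if isinstance(mc, MonteCarloSettings) else None
    data = simulate_mixture_dataset(
        net, sc, tracer, targets, kind=kind, flux_measurements=flux_measurements
    )
    # fit labelling rows at the nominal absolute error also used for the
    # continuation CIs (so the interval brackets the reported estimate);
    # rate-measurement rows keep the relative rule set when they were added.
    # Monte Carlo replicate noise follows its own max(rel*value, floor) rule.
    nominal = ci.nominal_sd if (ci is not None and ci.nominal_sd) else 0.001
    labelling = data.df["fragment_id"] != "@flux"
    data.df.loc[labelling, "sd"] = nominal

    fit = fit_fluxes(net, param, data, tracer, fit_settings)
    if mc_settings is not None:
        fit = monte_carlo_fit(
            net, param, data, tracer, mc_settings, fit_settings, base=fit
        )
    if ci is not None:
        continuation_ci(net, param, fit, data, tracer, ci)

    expected_state = weighted_average_flux(sc)
    expected_free = param.free_vector(expected_state)

    rows = []
    for i, name in enumerate(fit.free_names):
        lo_i, hi_i = (fit.ci or {}).get(name, (np.nan, np.nan))
        rows.append(
            {
                "quantity": name,
                "expected": expected_free[i],
                "estimate": fit.values[i],
                "ci_lo": lo_i,
                "ci_hi": hi_i,
                "percent": _percent(fit.values[i], expected_free[i]),
            }
        )

    if with_physiology is None:
        with_physiology = any(
            net.metabolites[m].role == "sink" and m.startswith("CO2")
            for m in net.metabolites
        )
    if with_physiology:
        est_state = complete_fluxes(param, fit.values, check_bounds=False)
        phys_exp = physiology_summary(net, expected_state)
        phys_est = physiology_summary(net, est_state)
        mc_phys = None
        if fit.mc_values is not None:
            mc_phys = np.array(
                [
                    _physiology_vector(
                        physiology_summary(
                            net, complete_fluxes(param, v, check_bounds=False)
                        )
                    )
                    for v in fit.mc_values
                ]
            )
        names = [
            "CO2 production",
            "O2 uptake",
            "Respiratory quotient",
            "Carbon conversion efficiency",
        ]
        exp_vec = _physiology_vector(phys_exp)
        est_vec = _physiology_vector(phys_est)
        for j, qname in enumerate(names):
            if mc_phys is not None:
                lo_j, hi_j = np.percentile(mc_phys[:, j], [2.5, 97.5])
            else:
                lo_j = hi_j = np.nan
            rows.append(
                {
                    "quantity": qname,
                    "expected": exp_vec[j],
                    "estimate": est_vec[j],
                    "ci_lo": lo_j,
                    "ci_hi": hi_j,
                    "percent": _percent(est_vec[j], exp_vec[j]),
                }
            )

    table = pd.DataFrame(rows)
    return ComparisonReport(scenario=sc.label, table=table, fit=fit)


def _physiology_vector(p: PhysiologySummary) -> np.ndarray:
    return np.array(
        [
            p.co2_production,
            p.o2_uptake,
            p.respiratory_quotient if p.respiratory_quotient is not None else np.nan,
            p.carbon_conversion_efficiency
            if p.carbon_conversion_efficiency is not None
            else np.nan,
        ]
    )


def reporter_equivalence_test(
    set_a: MeasurementSet, set_b: MeasurementSet
) -> dict[str, float]:
    """Are two measurement sets the same labelling?  Regression + paired t.

    Pools every shared isotopomer abundance, regresses B on A (equivalence
    predicts slope 1, intercept 0, R^2 near 1), and runs a paired t-test on
    the per-isotopomer differences (df = number of pairs - 1).
    """
    a = set_a.df[["fragment_id", "index", "value"]]
    b = set_b.df[["fragment_id", "index", "value"]]
    merged = a.merge(b, on=["fragment_id", "index"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared isotopomer abundances; need >= 3"
        )
    x = merged["value_a"].to_numpy()
    y = merged["value_b"].to_numpy()
    reg = stats.linregress(x, y)
    diffs = y - x
    if np.abs(diffs).max() < 1e-15:
        t_stat, p = 0.0, 1.0
    else:
        t_res = stats.ttest_rel(y, x)
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    return {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": float(reg.rvalue**2),
        "t": t_stat,
        "df": len(merged) - 1,
        "p": p,
        "n_pairs": len(merged),
    }


def make_balanced_scenario(
    param: FreeFluxParameterization,
    reference_free,
    member1_free,
    w1: float = 0.5,
    label: str = "",
) -> MixtureScenario:
    """Two-member scenario whose weighted mean equals a reference state.

    Solves member2 = (reference - w1 * member1) / w2 on the free net fluxes
    (exchange frees are taken from the reference for both members unless the
    member overrides them) and validates feasibility of both members.
    """
    reference_free = np.asarray(reference_free, dtype=float)
    member1_free = np.asarray(member1_free, dtype=float)
    w2 = 1.0 - w1
    if not 0.0 < w1 < 1.0:
        raise ValueError("w1 must be in (0, 1)")
    n_net = len(param.free_net_names)
    member2_free = reference_free.copy()
    member2_free[:n_net] = (reference_free[:n_net] - w1 * member1_free[:n_net]) / w2
    s1 = complete_fluxes(param, member1_free)
    s2 = complete_fluxes(param, member2_free)
    return MixtureScenario([(s1, w1), (s2, w2)], label=label)
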