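"""Free-flux estimation from labelling data.

Variance-weighted least squares over mass-isotopomer or positional-isotopomer
measurements, with Latin-hypercube multistart, Monte Carlo replicate fitting
(the 100-replicate, sd = max(1% of value, 0.001) protocol), and
parameter-continuation confidence intervals: each flux is stepped away from
the optimum with the remaining fluxes re-optimized until the SSR crosses the
chi-square threshold for the requested confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .midtools import MeasurementSet
from .network import (
    AtomTransitionNetwork,
    FluxState,
    FreeFluxParameterization,
    NetworkError,
)
from .simulate import (
    EMUSystem,
    FragmentTarget,
    SubstrateLabelling,
    decompose_emus,
    pattern_index,
    simulate_isotopomers_emu,
)

__all__ = [
    "FitSettings",
    "MonteCarloSettings",
    "CISettings",
    "FluxFitResult",
    "Objective",
    "ssr",
    "fit_fluxes",
    "monte_carlo_fit",
    "continuation_ci",
]


@dataclass
class FitSettings:
    multistart: int = 20
    tol: float = 1e-9
    seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass
class MonteCarloSettings:
    """Replicate protocol: noise sd = max(rel * value, floor) per measurement."""

    replicates: int = 100
    rel: float = 0.01
    floor: float = 0.001
    seed: int = 0
    multistart: int = 1

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.rel <= 0 or self.floor <= 0:
            raise ValueError("rel and floor must be positive")


@dataclass
class CISettings:
    level: float = 0.95
    nominal_sd: float | None = 0.001
    max_steps: int = 100
    rel_step: float = 0.02  # initial step as a fraction of the bound box

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")


@dataclass
class FluxFitResult:
    free_names: list[str]
    values: np.ndarray
    ssr: float
    residuals: np.ndarray
    optima: list[tuple[float, np.ndarray]] = field(default_factory=list)
    multimodal: bool = False
    n_started: int = 0
    n_converged: int = 0
    ci: dict[str, tuple[float, float]] | None = None
    ci_open: dict[str, tuple[bool, bool]] | None = None
    mc_mean: np.ndarray | None = None
    mc_sd: np.ndarray | None = None
    mc_values: np.ndarray | None = None
    mc_failed: int = 0

    def as_dict(self) -> dict:
        out = {
            "free_fluxes": dict(zip(self.free_names, map(float, self.values))),
            "ssr": float(self.ssr),
            "multimodal": self.multimodal,
            "n_converged": self.n_converged,
        }
        if self.ci is not None:
            out["ci"] = {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()}
        if self.mc_mean is not None:
            out["mc_mean"] = dict(zip(self.free_names, map(float, self.mc_mean)))
            out["mc_sd"] = dict(zip(self.free_names, map(float, self.mc_sd)))
        return out


_PENALTY = 1e3


class Objective:
    """Residual vector (sim - meas) / sd for one dataset.

    Pre-builds the EMU system and the row alignment once so repeated
    evaluations at new flux values only re-solve the linear cascades.
    Infeasible interior points (an irreversible net flux driven negative)
    return a smooth penalty pointing back toward the feasible region.
    """

    def __init__(
        self,
        net: AtomTransitionNetwork,
        param: FreeFluxParameterization,
        data: MeasurementSet,
        tracer: SubstrateLabelling,
    ):
        self.net = net
        self.param = param
        self.data = data
        self.tracer = tracer
        sd = data.df["sd"].to_numpy(dtype=float)
        if (sd <= 0).any():
            raise ValueError("all measurement SDs must be positive")
        self.sd = sd
        self.values = data.df["value"].to_numpy(dtype=float)

        self._irrev_rows = np.array(
            [
                i
                for i, r in enumerate(param.reaction_order)
                if not net.reactions[r].reversible
            ]
        )

        ids = [fid for fid in data.fragment_ids() if fid != "@flux"]
        if data.kind == "mid":
            targets = [data.targets[fid] for fid in ids]
            self.system = decompose_emus(net, targets)
            frag_pos = {fid: i for i, fid in enumerate(ids)}

            def locate(fid, idx):
                return (frag_pos[fid], int(str(idx)[1:]))

        elif data.kind == "isotopomer":
            self.metabolites = ids
            targets = []
            for m in ids:
                n = net.metabolites[m].n_carbons
                for mask in range(1, 2**n):
                    carbons = tuple(c + 1 for c in range(n) if (mask >> c) & 1)
                    targets.append(FragmentTarget(f"{m}#{mask}", ((m, carbons),)))
            self.system = decompose_emus(net, targets)
            met_pos = {m: i for i, m in enumerate(ids)}

            def locate(fid, idx):
                return (met_pos[fid], pattern_index(str(idx)))

        else:
            raise ValueError(f"unknown measurement kind {data.kind!r}")

        # row k of the dataframe -> either (panel position, entry index) or a
        # direct rate measurement of one reaction's net flux
        self._rows = [
            ("@flux", str(idx)) if fid == "@flux" else locate(fid, idx)
            for fid, idx in zip(data.df["fragment_id"], data.df["index"])
        ]

    def _flux_state(self, x: np.ndarray) -> FluxState | None:
        n_net = len(self.param.free_net_names)
        vnet = self.param.basis @ x[:n_net] + self.param.offset
        if self._irrev_rows.size:
            viol = -vnet[self._irrev_rows]
            self._violation = float(np.clip(viol, 0.0, None).sum())
            if self._violation > 1e-9:
                return None
        else:
            self._violation = 0.0
        net = dict(zip(self.param.reaction_order, vnet))
        xch = dict(zip(self.param.free_xch_names, x[n_net:]))
        return FluxState(net=net, xch01=xch)

    def _sim_vector(self, state: FluxState) -> np.ndarray:
        if self.data.kind == "mid":
            mids = self.system.fragment_mids(state, self.tracer)
            vecs = [m.abundances for m in mids]
        else:
            dists = simulate_isotopomers_emu(
                self.net, state, self.tracer, self.metabolites, system=self.system
            )
            vecs = [d.abundances for d in dists]
        return np.array(
            [
                state.net[j] if i == "@flux" else vecs[i][j]
                for i, j in self._rows
            ]
        )

    def simulate(self, x: np.ndarray) -> np.ndarray:
        """Simulated counterpart of every measurement row."""
        state = self._flux_state(np.asarray(x, dtype=float))
        if state is None:
            raise NetworkError("infeasible flux state")
        return self._sim_vector(state)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        state = self._flux_state(np.asarray(x, dtype=float))
        if state is None:
            return np.full(len(self.values), _PENALTY * (1.0 + self._violation))
        return (self._sim_vector(state) - self.values) / self.sd

    def ssr(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)


def ssr(
    net: AtomTransitionNetwork,
    param: FreeFluxParameterization,
    free_values,
    data: MeasurementSet,
    tracer: SubstrateLabelling,
    objective: Objective | None = None,
) -> float:
    """Variance-weighted sum of squared residuals at one free-flux vector."""
    if objective is None:
        objective = Objective(net, param, data, tracer)
    return objective.ssr(np.asarray(free_values, dtype=float))


def _finite_box(
    param: FreeFluxParameterization, override: dict | None
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = param.bounds_arrays()
    if override:
        for i, name in enumerate(param.free_names):
            if name in override:
                lo[i], hi[i] = override[name]
    lo = np.where(np.isfinite(lo), lo, -1e3)
    hi = np.where(np.isfinite(hi), hi, 1e3)
    return lo, hi


def fit_fluxes(
    net: AtomTransitionNetwork,
    param: FreeFluxParameterization,
    data: MeasurementSet,
    tracer: SubstrateLabelling,
    settings: FitSettings | None = None,
    objective: Objective | None = None,
    starts: list[np.ndarray] | None = None,
) -> FluxFitResult:
    """Best-fit free fluxes by multistart bounded least squares."""
    settings = settings or FitSettings()
    obj = objective or Objective(net, param, data, tracer)
    if len(obj.values) <= param.n_free:
        raise ValueError(
            f"{len(obj.values)} measurements cannot determine "
            f"{param.n_free} free fluxes"
        )
    lo, hi = _finite_box(param, settings.bounds)

    if starts is None:
        sampler = qmc.LatinHypercube(d=param.n_free, seed=settings.seed)
        pts = sampler.random(settings.multistart)
        starts = [lo + p * (hi - lo) for p in pts]

    optima: list[tuple[float, np.ndarray]] = []
    n_conv = 0
    for x0 in starts:
        try:
            res = least_squares(
                obj.residuals,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                xtol=settings.tol,
                ftol=settings.tol,
                gtol=settings.tol,
            )
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        n_conv += 1
        optima.append((float(2 * res.cost), res.x.copy()))
    if not optima:
        raise RuntimeError(
            f"no converged start out of {len(starts)} (bounds {lo}..{hi})"
        )
    optima.sort(key=lambda t: t[0])
    best_ssr, best_x = optima[0]
    near = [o for o in optima if o[0] <= best_ssr + 1e-6]
    scale = np.maximum(hi - lo, 1e-12)
    distinct: list[tuple[float, np.ndarray]] = []
    for s, x in near:
        if all(np.max(np.abs(x - dx) / scale) > 1e-5 for _, dx in distinct):
            distinct.append((s, x))
    result = FluxFitResult(
        free_names=list(param.free_names),
        values=best_x,
        ssr=best_ssr,
        residuals=obj.residuals(best_x),
        optima=distinct,
        multimodal=len(distinct) > 1,
        n_started=len(starts),
        n_converged=n_conv,
    )
    return result


def monte_carlo_fit(
    net: AtomTransitionNetwork,
    param: FreeFluxParameterization,
    data: MeasurementSet,
    tracer: SubstrateLabelling,
    mc: MonteCarloSettings | None = None,
    settings: FitSettings | None = None,
    base: FluxFitResult | None = None,
) -> FluxFitResult:
    """Replicate fits to noise-perturbed copies of the dataset.

    Each replicate redraws every measurement with sd = max(rel*value, floor),
    refits starting from the base optimum, and the per-flux mean and SD over
    replicates quantify estimate reliability.  Fully reproducible under a
    fixed seed; isolated fit failures are counted, not fatal (up to 10%).
    """
    mc = mc or MonteCarloSettings()
    settings = settings or FitSettings()
    obj = Objective(net, param, data, tracer)
    if base is None:
        base = fit_fluxes(net, param, data, tracer, settings, objective=obj)

    rng = np.random.default_rng(mc.seed)
    truth = data.df["value"].to_numpy(dtype=float)
    noise_sd = np.maximum(mc.rel * np.abs(truth), mc.floor)
    lo, hi = _finite_box(param, settings.bounds)
    sampler = qmc.LatinHypercube(d=param.n_free, seed=mc.seed)

    draws = []
    failed = 0
    rep_settings = FitSettings(
        multistart=mc.multistart, tol=settings.tol, seed=mc.seed
    )
    for _ in range(mc.replicates):
        # noise magnitude follows the replicate rule; the declared
        # measurement weighting of the dataset is left untouched
        perturbed = data.copy()
        perturbed.df["value"] = truth + rng.normal(0.0, noise_sd)
        robj = Objective(net, param, perturbed, tracer)
        starts = [base.values.copy()]
        if mc.multistart > 1:
            pts = sampler.random(mc.multistart - 1)
            starts += [lo + p * (hi - lo) for p in pts]
        try:
            rep = fit_fluxes(
                net, param, perturbed, tracer, rep_settings,
                objective=robj, starts=starts,
            )
            draws.append(rep.values)
        except Exception:
            failed += 1
    if failed > 0.1 * mc.replicates:
        raise RuntimeError(f"{failed}/{mc.replicates} Monte Carlo fits failed")

    arr = np.array(draws)
    out = FluxFitResult(
        free_names=base.free_names,
        values=base.values,
        ssr=base.ssr,
        residuals=base.residuals,
        optima=base.optima,
        multimodal=base.multimodal,
        n_started=base.n_started,
        n_converged=base.n_converged,
        ci=base.ci,
        ci_open=base.ci_open,
        mc_mean=arr.mean(axis=0),
        mc_sd=arr.std(axis=0, ddof=1),
        mc_values=arr,
        mc_failed=failed,
    )
    return out


def _reoptimize_fixed(
    obj: Objective,
    x_full: np.ndarray,
    fixed_idx: int,
    fixed_value: float,
    lo: np.ndarray,
    hi: np.ndarray,
    tol: float,
) -> tuple[float, np.ndarray]:
    """SSR minimized over all free fluxes except one held fixed."""
    free_idx = [i for i in range(len(x_full)) if i != fixed_idx]

    def expand(xr: np.ndarray) -> np.ndarray:
        full = np.empty(len(x_full))
        full[fixed_idx] = fixed_value
        full[free_idx] = xr
        return full

    if not free_idx:
        full = expand(np.array([]))
        return obj.ssr(full), full

    res = least_squares(
        lambda xr: obj.residuals(expand(xr)),
        np.clip(x_full[free_idx], lo[free_idx], hi[free_idx]),
        bounds=(lo[free_idx], hi[free_idx]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
    )
    return float(2 * res.cost), expand(res.x)


def _refine_crossing(
    obj: Objective,
    x_start: np.ndarray,
    idx: int,
    lo: np.ndarray,
    hi: np.ndarray,
    tol: float,
    ssr_min: float,
    threshold: float,
    v_in: float,
    s_in: float,
    v_out: float,
    s_out: float,
    iters: int = 5,
) -> float:
    """Locate the SSR threshold crossing between a bracketing pair.

    Interpolates on sqrt(SSR - SSR_min), which is exact for a locally
    quadratic profile, and tightens the bracket a few times.
    """
    target = np.sqrt(max(threshold - ssr_min, 0.0))
    for _ in range(iters):
        g_in = np.sqrt(max(s_in - ssr_min, 0.0))
        g_out = np.sqrt(max(s_out - ssr_min, 0.0))
        if g_out <= g_in:
            break
        v_mid = v_in + (v_out - v_in) * (target - g_in) / (g_out - g_in)
        if not (min(v_in, v_out) < v_mid < max(v_in, v_out)):
            break
        s_mid, x_start = _reoptimize_fixed(obj, x_start, idx, v_mid, lo, hi, tol)
        if abs(s_mid - threshold) < 1e-4 * (threshold - ssr_min):
            return v_mid
        if s_mid > threshold:
            v_out, s_out = v_mid, s_mid
        else:
            v_in, s_in = v_mid, s_mid
    g_in = np.sqrt(max(s_in - ssr_min, 0.0))
    g_out = np.sqrt(max(s_out - ssr_min, 0.0))
    if g_out > g_in:
        return v_in + (v_out - v_in) * (target - g_in) / (g_out - g_in)
    return 0.5 * (v_in + v_out)


def continuation_ci(
    net: AtomTransitionNetwork,
    param: FreeFluxParameterization,
    fit: FluxFitResult,
    data: MeasurementSet,
    tracer: SubstrateLabelling,
    ci: CISettings | None = None,
    tol: float = 1e-10,
) -> dict[str, tuple[float, float]]:
    """Parameter-continuation confidence intervals.

    Each free flux is stepped away from the optimum while the others are
    re-optimized; the interval boundary is where the SSR profile crosses
    SSR_min + chi2(1, level) (3.84 at 95%).  The step halves on overshoot
    and the crossing is refined by inverse linear interpolation.  A profile
    still below the threshold at a free-flux bound yields an open interval
    side, flagged in ``fit.ci_open``.
    """
    ci = ci or CISettings()
    work = data.copy()
    if ci.nominal_sd is not None:
        # the nominal absolute error applies to labelling abundances; direct
        # rate measurements keep their own uncertainty
        labelling = work.df["fragment_id"] != "@flux"
        work.df.loc[labelling, "sd"] = ci.nominal_sd
    obj = Objective(net, param, work, tracer)
    lo, hi = _finite_box(param, None)

    # re-polish the optimum under the nominal error model
    res = least_squares(
        obj.residuals,
        np.clip(fit.values, lo, hi),
        bounds=(lo, hi),
        xtol=tol, ftol=tol, gtol=tol,
    )
    x_min = res.x
    ssr_min = float(2 * res.cost)
    threshold = ssr_min + stats.chi2.ppf(ci.level, df=1)

    intervals: dict[str, tuple[float, float]] = {}
    open_flags: dict[str, tuple[bool, bool]] = {}
    for i, name in enumerate(fit.free_names):
        sides = []
        flags = []
        for direction in (-1.0, +1.0):
            bound = lo[i] if direction < 0 else hi[i]
            step = ci.rel_step * (hi[i] - lo[i])
            x_cur = x_min.copy()
            s_cur = ssr_min
            v_cur = x_min[i]
            crossing = None
            is_open = False
            for _ in range(ci.max_steps):
                v_trial = v_cur + direction * step
                hit_bound = (direction < 0 and v_trial <= bound) or (
                    direction > 0 and v_trial >= bound
                )
                if hit_bound:
                    v_trial = bound
                s_trial, x_trial = _reoptimize_fixed(
                    obj, x_cur, i, v_trial, lo, hi, tol
                )
                if s_trial > threshold:
                    if s_trial > ssr_min + 4 * (threshold - ssr_min) and step > 1e-12 * (hi[i] - lo[i]):
                        step *= 0.5  # overshot far past the threshold: refine
                        continue
                    crossing = _refine_crossing(
                        obj, x_trial, i, lo, hi, tol, ssr_min, threshold,
                        v_cur, s_cur, v_trial, s_trial,
                    )
                    break
                v_cur, s_cur, x_cur = v_trial, s_trial, x_trial
                if hit_bound:
                    crossing = bound
                    is_open = True
                    break
                step *= 1.6
            if crossing is None:
                crossing = v_cur
                is_open = True
            sides.append(crossing)
            flags.append(is_open)
        intervals[name] = (min(sides), max(sides))
        open_flags[name] = (flags[0], flags[1])

    fit.ci = intervals
    fit.ci_open = open_flags
    return intervals
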