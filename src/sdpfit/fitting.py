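"""Joint multi-contrast ensemble fitting.

One membrane structure is refined simultaneously against an x-ray curve and
up to three neutron contrasts.  The cost is a weighted joint chi-square over
all fitted q-windows, with per-dataset intensity scale and flat background
profiled analytically (weighted linear least squares) and soft penalties for
unphysical packing (total volume probability above 1, negative methylene
probability).  The global search is a genetic algorithm; robustness and
uncertainties come from an *ensemble* of independent GA runs with random
starting populations: the reported estimate of each parameter is the center
of mass of its distribution over runs, the uncertainty the square root of
the second central moment.

The statsmodels-style surface is :class:`JointSDPModel` (data + parameter
specs, ``fit()``) returning an :class:`EnsembleFitResult` (estimates,
uncertainties, run table, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bilayer import DEFAULT_STRUCTURE_PARAMS, SDPModel, build_unit_cell
from .composition import PeptideSpec, Solvent
from .datasets import DataError, ScatteringDataset
from .formfactor import form_factor_analytic

__all__ = [
    "FitParameterSpec",
    "GAConfig",
    "CostOptions",
    "FitError",
    "JointSDPModel",
    "EnsembleFitResult",
    "default_parameter_specs",
    "cost",
    "ga_minimize",
    "ensemble_fit",
    "aggregate",
]


class FitError(RuntimeError):
    """Fit setup or convergence failure."""


@dataclass(frozen=True)
class FitParameterSpec:
    """One adjustable (or fixed) model parameter with box bounds."""

    name: str
    lo: float
    hi: float
    fixed: bool = False
    value: float | None = None  # required when fixed

    def __post_init__(self):
        if not self.fixed and not self.lo < self.hi:
            raise FitError(f"{self.name}: need lo < hi, got [{self.lo}, {self.hi}]")
        if self.fixed and self.value is None:
            raise FitError(f"{self.name}: fixed parameter needs a value")


def default_parameter_specs(with_peptide: bool) -> list[FitParameterSpec]:
    """Default free parameters: A_U, headgroup z/sigma, sigma_HC (+ z_p, sigma_p).

    Group volumes, the CH/CH3 widths and the CH position fraction stay fixed
    (standard SDP practice, keeping the problem determined at 4 contrasts);
    per-dataset scale and background are profiled analytically and never
    appear here.
    """
    specs = [
        FitParameterSpec("A_U", 55.0, 70.0),
        FitParameterSpec("z_ENX", 15.0, 25.0),
        FitParameterSpec("sigma_ENX", 1.5, 5.0),
        FitParameterSpec("z_PG2", 15.0, 25.0),
        FitParameterSpec("sigma_PG2", 1.5, 5.0),
        FitParameterSpec("z_PO4", 15.0, 24.0),
        FitParameterSpec("sigma_PO4", 1.5, 4.0),
        FitParameterSpec("z_CG", 12.0, 18.0),
        FitParameterSpec("sigma_CG", 1.5, 4.0),
        FitParameterSpec("sigma_HC", 1.5, 3.5),
    ]
    if with_peptide:
        specs += [
            FitParameterSpec("z_p", 8.0, 22.0),
            FitParameterSpec("sigma_p", 2.5, 8.0),
        ]
    return specs


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm knobs (tournament selection, uniform crossover,
    per-gene Gaussian mutation, elitism)."""

    population: int = 64
    generations: int = 300
    tournament: int = 3
    crossover_p: float = 0.7
    mutation_p: float = 0.1
    mutation_sigma: float = 0.1    # fraction of each parameter's range
    mutation_decay: float = 0.985  # per-generation annealing of the step
    elitism: int = 2
    patience: int = 40             # early stop after this many flat generations
    tol: float = 1e-6              # relative improvement counted as progress
    polish: bool = False           # L-BFGS-B refinement from the GA best


@dataclass(frozen=True)
class CostOptions:
    """Penalty weights and packing tolerances for the joint cost."""

    overfill_tol: float = 0.02       # allowed total-probability excess
    ch2_negative_tol: float = 0.02   # allowed negative CH2 dip
    penalty_weight: float = 1.0e4    # quadratic penalty scale
    z_max: float = 45.0              # penalty-grid extent, A
    z_step: float = 0.5


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

def _profile_scale_background(
    y: np.ndarray, I: np.ndarray, w: np.ndarray,
    fixed_scale: float | None, fixed_background: float | None,
) -> tuple[float, float]:
    """Weighted linear LS of I ~ s*y + b (either may be held fixed)."""
    if fixed_scale is not None and fixed_background is not None:
        return fixed_scale, fixed_background
    if fixed_scale is not None:
        b = np.sum(w * (I - fixed_scale * y)) / np.sum(w)
        return fixed_scale, float(b)
    if fixed_background is not None:
        s = np.sum(w * y * (I - fixed_background)) / np.sum(w * y * y)
        return float(max(s, 1e-30)), fixed_background
    sw, swy = np.sum(w), np.sum(w * y)
    swyy, swI, swyI = np.sum(w * y * y), np.sum(w * I), np.sum(w * y * I)
    det = sw * swyy - swy * swy
    if det <= 0 or not np.isfinite(det):
        return 1e-30, float(swI / sw)
    s = (sw * swyI - swy * swI) / det
    b = (swyy * swI - swy * swyI) / det
    if s <= 0:  # scale must stay positive; refit background alone
        s = 1e-30
        b = float(swI / sw)
    return float(s), float(b)


def _packing_penalty(model: SDPModel, opts: CostOptions,
                     z: np.ndarray | None = None) -> float:
    from .bilayer import volume_probability

    if z is None:
        z = np.arange(0.0, opts.z_max + opts.z_step, opts.z_step)
    prof = volume_probability(model, z)
    excess = max(float((prof.total - 1.0).max()), 0.0)
    pen = max(excess - opts.overfill_tol, 0.0) ** 2
    pen += max(-prof.ch2_min - opts.ch2_negative_tol, 0.0) ** 2
    return opts.penalty_weight * pen


def cost(
    params: dict[str, float],
    datasets: list[ScatteringDataset],
    model_builder,
    options: CostOptions | None = None,
    return_details: bool = False,
):
    """Weighted joint chi-square plus packing penalties.

    ``model_builder`` maps a parameter dict to an :class:`SDPModel`.  Scale
    and background of each dataset are profiled analytically unless the
    dataset fixes them.
    """
    opts = options or CostOptions()
    try:
        model = model_builder(params)
    except Exception:
        return (np.inf, {}) if return_details else np.inf

    chi2 = 0.0
    details = {}
    for ds in datasets:
        dsw = ds.windowed()
        if dsw.q.size == 0:
            raise DataError(f"{ds.label()}: empty fit window")
        ff = form_factor_analytic(model, ds.probe, ds.x_D, dsw.q)
        y = ff.F**2 / dsw.q**2
        w = 1.0 / dsw.sigma**2
        s, b = _profile_scale_background(y, dsw.I, w, ds.scale, ds.background)
        resid = (s * y + b - dsw.I) / dsw.sigma
        chi2 += ds.weight * float(np.sum(resid**2))
        if return_details:
            details[ds.label()] = {"scale": s, "background": b,
                                   "chi2": float(np.sum(resid**2)),
                                   "n": int(dsw.q.size)}
    total = chi2 + _packing_penalty(model, opts)
    if return_details:
        return total, details
    return total


class _FastCost:
    """Vectorised joint-cost evaluator equivalent to the reference path.

    Stacks all Gaussian components into arrays so one candidate costs a
    handful of numpy operations instead of per-component Python calls.
    Scattering densities per contrast are precomputed (group compositions
    and solvent are fixed during a fit); only A_U and the positions/widths
    vary.  Equivalence with :func:`cost` over random parameter draws is
    pinned by the test suite.
    """

    _HEAD_KEYS = ("ENX", "PG2", "PO4", "CG")

    def __init__(self, model: "JointSDPModel"):
        from .formfactor import _solvent_at, _solvent_sld, group_sld
        from .bilayer import combine_peptides

        self.opts = model.cost_options
        self.z_pen = model._penalty_z
        groups = model.groups
        f = model.lipid_fractions
        mult = {"ENX": f.get("POPE", 0.0), "PG2": f.get("POPG", 0.0),
                "PO4": 1.0, "CG": 1.0}
        self.heads = [k for k in self._HEAD_KEYS if mult.get(k, 0.0) > 0]
        self.V_heads = np.array(
            [groups[k].volume * mult[k] for k in self.heads])
        self.V_CH = groups["CH"].volume * groups["CH"].multiplicity
        self.V_CH3 = groups["CH3"].volume * groups["CH3"].multiplicity
        self.V_HC = (groups["CH2"].volume * groups["CH2"].multiplicity
                     + self.V_CH + self.V_CH3)
        self.PL = model.PL_ratio
        pep = None
        if self.PL > 0:
            pep = model._peptides_built[0] if len(model._peptides_built) == 1 \
                else combine_peptides(model._peptides_built)
        self.V_pep = pep.volume * self.PL if pep is not None else 0.0

        self.data = []
        for ds, dsw in zip(model.datasets, model._windowed):
            solv = _solvent_at_model(model.solvent, dsw.x_D)
            rho_s = _solvent_sld(dsw.probe, solv)
            rho_heads = np.array(
                [group_sld(groups[k], dsw.probe, solv) for k in self.heads])
            rho_ch2 = group_sld(groups["CH2"], dsw.probe, solv)
            entry = {
                "q": dsw.q, "q2": dsw.q**2, "I": dsw.I,
                "w": 1.0 / dsw.sigma**2, "sigma": dsw.sigma,
                "weight": ds.weight, "scale": ds.scale, "bg": ds.background,
                # contrast coefficients: heads & peptide vs. solvent,
                # CH/CH3 vs. the CH2 background, CH2 vs. solvent
                "d_heads": rho_heads - rho_s,
                "d_CH": group_sld(groups["CH"], dsw.probe, solv) - rho_ch2,
                "d_CH3": group_sld(groups["CH3"], dsw.probe, solv) - rho_ch2,
                "d_CH2": rho_ch2 - rho_s,
                "d_pep": (group_sld(pep, dsw.probe, solv) - rho_s)
                if pep is not None else 0.0,
            }
            self.data.append(entry)

    def _geometry(self, p: dict[str, float]):
        A = p["A_U"]
        D_C = self.V_HC / A
        zc = [p[f"z_{k}"] for k in self.heads]
        sg = [p[f"sigma_{k}"] for k in self.heads]
        zc += [p["f_CH"] * D_C, 0.0]
        sg += [p["sigma_CH"], p["sigma_CH3"]]
        V = list(self.V_heads) + [self.V_CH, self.V_CH3]
        if self.PL > 0:
            zc.append(p["z_p"])
            sg.append(p["sigma_p"])
            V.append(self.V_pep)
        return (A, D_C, np.asarray(zc), np.asarray(sg), np.asarray(V))

    def __call__(self, p: dict[str, float]) -> float:
        from .bilayer import SIGMA_MIN

        A, D_C, zc, sg, V = self._geometry(p)
        if A <= 0 or np.any(sg < SIGMA_MIN - 1e-12) \
                or p["sigma_HC"] < SIGMA_MIN - 1e-12 or np.any(zc < 0):
            return np.inf
        n_h = len(self.heads)
        chi2 = 0.0
        for d in self.data:
            q = d["q"]
            amp = (2.0 * V / A)[:, None] * np.cos(np.outer(zc, q)) \
                * np.exp(np.outer(sg**2, -0.5 * d["q2"]))
            drho = np.concatenate(
                [d["d_heads"], [d["d_CH"], d["d_CH3"]],
                 [d["d_pep"]] if self.PL > 0 else []])
            env = 2.0 * np.sin(q * D_C) / q * np.exp(
                -0.5 * d["q2"] * p["sigma_HC"] ** 2)
            F = drho @ amp + d["d_CH2"] * env
            y = F**2 / d["q2"]
            s, b = _profile_scale_background(y, d["I"], d["w"],
                                             d["scale"], d["bg"])
            resid = (s * y + b - d["I"]) / d["sigma"]
            chi2 += d["weight"] * float(resid @ resid)
        return chi2 + self._penalty(p, A, D_C, zc, sg, V, n_h)

    def residuals(self, p: dict[str, float]) -> np.ndarray:
        """Concatenated weighted residual vector (penalty as last entry)."""
        from .bilayer import SIGMA_MIN

        A, D_C, zc, sg, V = self._geometry(p)
        if A <= 0 or np.any(sg < SIGMA_MIN - 1e-12) \
                or p["sigma_HC"] < SIGMA_MIN - 1e-12 or np.any(zc < 0):
            raise FitError("parameters outside the model domain")
        out = []
        for d in self.data:
            q = d["q"]
            amp = (2.0 * V / A)[:, None] * np.cos(np.outer(zc, q)) \
                * np.exp(np.outer(sg**2, -0.5 * d["q2"]))
            drho = np.concatenate(
                [d["d_heads"], [d["d_CH"], d["d_CH3"]],
                 [d["d_pep"]] if self.PL > 0 else []])
            env = 2.0 * np.sin(q * D_C) / q * np.exp(
                -0.5 * d["q2"] * p["sigma_HC"] ** 2)
            F = drho @ amp + d["d_CH2"] * env
            y = F**2 / d["q2"]
            s, b = _profile_scale_background(y, d["I"], d["w"],
                                             d["scale"], d["bg"])
            out.append(np.sqrt(d["weight"]) * (s * y + b - d["I"]) / d["sigma"])
        n_h = len(self.heads)
        pen = self._penalty(p, A, D_C, zc, sg, V, n_h)
        out.append(np.array([math.sqrt(pen)]))
        return np.concatenate(out)

    def _penalty(self, p, A, D_C, zc, sg, V, n_h) -> float:
        from scipy.special import erf

        z = self.z_pen
        coef = V / (A * sg * math.sqrt(2 * math.pi))
        gauss = coef[:, None] * (
            np.exp(-((z[None, :] - zc[:, None]) ** 2) / (2 * sg[:, None] ** 2))
            + np.exp(-((z[None, :] + zc[:, None]) ** 2) / (2 * sg[:, None] ** 2)))
        s = p["sigma_HC"] * math.sqrt(2.0)
        env = 0.5 * (erf((D_C - z) / s) + erf((D_C + z) / s))
        total = gauss[:n_h].sum(axis=0) + env
        if self.PL > 0:
            total = total + gauss[-1]
        excess = max(float(total.max()) - 1.0, 0.0)
        ch2_min = min(float((env - gauss[n_h] - gauss[n_h + 1]).min()), 0.0)
        opts = self.opts
        pen = max(excess - opts.overfill_tol, 0.0) ** 2
        pen += max(-ch2_min - opts.ch2_negative_tol, 0.0) ** 2
        return opts.penalty_weight * pen


def _solvent_at_model(solvent: Solvent, x_D: float) -> Solvent:
    return Solvent(x_D=x_D, V_W=solvent.V_W)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class SingleFit:
    params: dict[str, float]
    x: np.ndarray
    cost: float
    n_generations: int
    seed: int


class _ParamMap:
    """Vector <-> dict translation for the free parameters."""

    def __init__(self, specs: list[FitParameterSpec]):
        self.free = [s for s in specs if not s.fixed]
        self.fixed = {s.name: s.value for s in specs if s.fixed}
        self.names = [s.name for s in self.free]
        self.lo = np.array([s.lo for s in self.free])
        self.hi = np.array([s.hi for s in self.free])

    @property
    def n(self) -> int:
        return len(self.free)

    def to_params(self, x: np.ndarray) -> dict[str, float]:
        p = {n: float(v) for n, v in zip(self.names, x)}
        p.update(self.fixed)
        return p


def ga_minimize(
    cost_fn,
    specs: list[FitParameterSpec],
    seed: int,
    ga_config: GAConfig | None = None,
) -> SingleFit:
    """One genetic-algorithm run; deterministic given ``seed`` and config.

    ``cost_fn`` takes a parameter dict and returns a scalar.  Candidates are
    clipped to bounds after mutation.  Raises :class:`FitError` if no initial
    candidate has finite cost.
    """
    cfg = ga_config or GAConfig()
    pm = _ParamMap(specs)
    if pm.n == 0:
        raise FitError("no free parameters")
    rng = np.random.default_rng(seed)
    span = pm.hi - pm.lo

    pop = pm.lo + rng.random((cfg.population, pm.n)) * span
    fit = np.array([cost_fn(pm.to_params(x)) for x in pop])
    if not np.isfinite(fit).any():
        raise FitError("cost not finite at any initial candidate")

    best = float(fit.min())
    stall = 0
    gen = 0
    sigma_gen = cfg.mutation_sigma
    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fit)
        elite = pop[order[: cfg.elitism]]

        n_child = cfg.population - cfg.elitism
        # tournament selection of two parent pools
        idx = rng.integers(0, cfg.population, size=(2, n_child, cfg.tournament))
        winners = idx[
            np.arange(2)[:, None, None],
            np.arange(n_child)[None, :, None],
            np.argmin(fit[idx], axis=2)[:, :, None],
        ][:, :, 0]
        pa, pb = pop[winners[0]], pop[winners[1]]
        # uniform crossover
        take_b = (rng.random((n_child, pm.n)) < 0.5) \
            & (rng.random((n_child, 1)) < cfg.crossover_p)
        children = np.where(take_b, pb, pa)
        # per-gene Gaussian mutation
        mutate = rng.random((n_child, pm.n)) < cfg.mutation_p
        children = children + mutate * rng.normal(
            0.0, sigma_gen, size=(n_child, pm.n)) * span
        children = np.clip(children, pm.lo, pm.hi)
        sigma_gen *= cfg.mutation_decay

        pop = np.vstack([elite, children])
        fit = np.concatenate([
            fit[order[: cfg.elitism]],
            [cost_fn(pm.to_params(x)) for x in children],
        ])

        new_best = float(fit.min())
        if best - new_best > cfg.tol * max(abs(best), 1.0):
            best, stall = new_best, 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    i = int(np.argmin(fit))
    x_best, f_best = pop[i].copy(), float(fit[i])

    if cfg.polish:
        from scipy.optimize import minimize

        res = minimize(
            lambda x: cost_fn(pm.to_params(x)), x_best, method="L-BFGS-B",
            bounds=list(zip(pm.lo, pm.hi)))
        if np.isfinite(res.fun) and res.fun < f_best:
            x_best, f_best = np.clip(res.x, pm.lo, pm.hi), float(res.fun)

    return SingleFit(params=pm.to_params(x_best), x=x_best, cost=f_best,
                     n_generations=gen, seed=seed)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleFitResult:
    """Distributions over independent GA runs and their moment summaries.

    ``params`` holds the center-of-mass estimates, ``uncertainties`` the
    square roots of the second central moments.
    """

    names: list[str]
    runs: np.ndarray            # (n_runs, n_free) best vector per run
    costs: np.ndarray           # (n_runs,)
    seeds: np.ndarray
    specs: list[FitParameterSpec] = field(default_factory=list)
    model: "JointSDPModel | None" = None
    n_failed: int = 0

    def __post_init__(self):
        est, unc = aggregate_arrays(self.runs)
        self.params = pd.Series(est, index=self.names)
        self.uncertainties = pd.Series(unc, index=self.names)

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def best(self) -> dict[str, float]:
        i = int(np.argmin(self.costs))
        p = {n: float(v) for n, v in zip(self.names, self.runs[i])}
        if self.model is not None:
            p.update(self.model.param_map.fixed)
        return p

    def param_dict(self) -> dict[str, float]:
        p = {n: float(v) for n, v in self.params.items()}
        if self.model is not None:
            p.update(self.model.param_map.fixed)
        return p

    def run_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=self.names)
        df.insert(0, "seed", self.seeds)
        df["cost"] = self.costs
        return df

    def plot_fit(self, path=None):
        from .plotting import plot_fit

        return plot_fit(self, path=path)

    def mean_model(self) -> SDPModel:
        if self.model is None:
            raise FitError("result is not attached to a JointSDPModel")
        return self.model.build(self.param_dict())

    def structure_report(self, reference=None):
        from .report import StructureReport

        rep = StructureReport.from_ensemble(self)
        if reference is not None:
            from .report import compare_to_reference

            return rep, compare_to_reference(rep, reference)
        return rep

    def summary(self) -> str:
        lines = [
            "Joint SDP ensemble fit",
            f"  runs: {self.n_runs} (failed: {self.n_failed})",
            f"  best cost: {self.costs.min():.4g}   "
            f"median cost: {np.median(self.costs):.4g}",
            "",
            f"  {'parameter':<12} {'estimate':>10} {'+/-':>9}",
        ]
        for n in self.names:
            lines.append(
                f"  {n:<12} {self.params[n]:>10.4f} {self.uncertainties[n]:>9.4f}")
        return "\n".join(lines)


def aggregate_arrays(runs: np.ndarray, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Center of mass and second-central-moment width over runs."""
    w = np.ones(runs.shape[0]) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    est = w @ runs
    var = w @ (runs - est) ** 2
    return est, np.sqrt(var)


def aggregate(result: EnsembleFitResult, weights=None) -> pd.DataFrame:
    """Parameter table (estimate +/- uncertainty) from the run ensemble."""
    est, unc = aggregate_arrays(result.runs, weights)
    return pd.DataFrame({"estimate": est, "uncertainty": unc}, index=result.names)


def ensemble_fit(
    cost_fn,
    specs: list[FitParameterSpec],
    n_runs: int = 400,
    base_seed: int = 0,
    ga_config: GAConfig | None = None,
    n_jobs: int = 1,
) -> EnsembleFitResult:
    """``n_runs`` independent GA runs with seeds spawned from ``base_seed``.

    Seeds are drawn once from a SeedSequence, so run *i* gets the same seed
    whether the ensemble executes serially or in parallel.  Fails if more
    than half of the runs error out.
    """
    if n_runs < 1:
        raise FitError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs)

    def one(seed):
        try:
            return ga_minimize(cost_fn, specs, int(seed), ga_config)
        except FitError:
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in seeds)
    else:
        results = [one(s) for s in seeds]

    ok = [r for r in results if r is not None]
    if len(ok) < max(1, n_runs // 2):
        raise FitError(f"only {len(ok)}/{n_runs} GA runs succeeded")
    pm = _ParamMap(specs)
    runs = np.array([r.x for r in ok])
    return EnsembleFitResult(
        names=pm.names,
        runs=runs,
        costs=np.array([r.cost for r in ok]),
        seeds=np.array([r.seed for r in ok]),
        specs=list(specs),
        n_failed=n_runs - len(ok),
    )


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class JointSDPModel:
    """Joint SAXS/SANS SDP model bound to a set of scattering datasets.

    Parameters
    ----------
    datasets : list of ScatteringDataset
        One entry per contrast (x-ray at x_D = 0, neutrons at their D2O
        fractions), each with its own fit window and weight.
    peptides : list of PeptideSpec, optional
        Peptides adsorbed at ``PL_ratio`` peptides per lipid; mixtures are
        merged into a single Gaussian with averaged composition.
    param_specs : list of FitParameterSpec, optional
        Defaults to :func:`default_parameter_specs`.
    fixed_params : dict, optional
        Structural parameters held at non-default fixed values (e.g.
        ``{"f_CH": 0.45}``).
    """

    def __init__(
        self,
        datasets: list[ScatteringDataset],
        peptides: list[PeptideSpec] | None = None,
        PL_ratio: float = 0.0,
        lipid_fractions: dict[str, float] | None = None,
        param_specs: list[FitParameterSpec] | None = None,
        fixed_params: dict[str, float] | None = None,
        groups=None,
        solvent: Solvent | None = None,
        cost_options: CostOptions | None = None,
    ):
        if not datasets:
            raise DataError("need at least one dataset")
        self.datasets = list(datasets)
        self._windowed = [ds.windowed() for ds in self.datasets]
        self.peptides = list(peptides or [])
        self._peptides_built = self.peptides
        if len(self.peptides) > 1:
            from .bilayer import combine_peptides

            self._peptides_built = [combine_peptides(self.peptides)]
        self.PL_ratio = PL_ratio
        self.lipid_fractions = lipid_fractions or {"POPE": 0.75, "POPG": 0.25}
        if groups is None:
            from .composition import default_lipid_groups

            groups = default_lipid_groups()
        self.groups = groups
        self.solvent = solvent or Solvent()
        self.cost_options = cost_options or CostOptions()
        self.fixed_params = dict(fixed_params or {})
        self.param_specs = list(
            param_specs
            if param_specs is not None
            else default_parameter_specs(with_peptide=PL_ratio > 0))
        self.param_map = _ParamMap(self.param_specs)
        self._base_params = dict(DEFAULT_STRUCTURE_PARAMS)
        self._base_params.update(self.fixed_params)
        opts = self.cost_options
        self._penalty_z = np.arange(0.0, opts.z_max + opts.z_step, opts.z_step)
        self._fast = _FastCost(self)

    @classmethod
    def from_study(cls, manifest_path, **kwargs) -> "JointSDPModel":
        """Build from a study manifest written by :func:`sdpfit.simulate.make_study`."""
        from .composition import default_peptides
        from .simulate import load_study

        manifest, datasets = load_study(manifest_path)
        library = default_peptides()
        peptides = [library[n] for n in manifest.get("peptides", [])]
        return cls(
            datasets,
            peptides=peptides,
            PL_ratio=manifest.get("PL_ratio", 0.0),
            lipid_fractions=manifest.get("lipid_fractions"),
            **kwargs,
        )

    def build(self, params: dict[str, float]) -> SDPModel:
        """SDPModel for one structural parameter dict."""
        p = {**self._base_params, **params}
        return build_unit_cell(
            lipid_fractions=self.lipid_fractions,
            peptides=self._peptides_built,
            PL_ratio=self.PL_ratio,
            params=p,
            groups=self.groups,
            solvent=self.solvent,
        )

    def cost(self, params: dict[str, float], return_details: bool = False):
        """Joint chi-square + penalties (vectorised fast path)."""
        if not return_details:
            return self._fast({**self._base_params, **params})
        opts = self.cost_options
        try:
            model = self.build(params)
        except Exception:
            return (np.inf, {}) if return_details else np.inf
        chi2 = 0.0
        details = {}
        for ds, dsw in zip(self.datasets, self._windowed):
            ff = form_factor_analytic(model, dsw.probe, dsw.x_D, dsw.q)
            y = ff.F**2 / dsw.q**2
            w = 1.0 / dsw.sigma**2
            s, b = _profile_scale_background(y, dsw.I, w, ds.scale, ds.background)
            resid = (s * y + b - dsw.I) / dsw.sigma
            chi2 += ds.weight * float(np.sum(resid**2))
            if return_details:
                details[ds.label()] = {"scale": s, "background": b,
                                       "chi2": float(np.sum(resid**2)),
                                       "n": int(dsw.q.size)}
        total = chi2 + _packing_penalty(model, opts, self._penalty_z)
        if return_details:
            return total, details
        return total

    def fit_single(self, seed: int = 0, ga_config: GAConfig | None = None) -> SingleFit:
        return ga_minimize(self.cost, self.param_specs, seed, ga_config)

    def polish(self, params: dict[str, float]) -> SingleFit:
        """Trust-region least-squares refinement of a parameter dict.

        Minimises the weighted residual vector directly (scipy
        ``least_squares``/TRF within bounds), which descends the narrow
        chi-square valleys far more effectively than scalar methods; used
        for convergence checks, not for ensemble statistics.
        """
        from scipy.optimize import least_squares

        pm = self.param_map
        x0 = np.clip(np.array([params[n] for n in pm.names]), pm.lo, pm.hi)

        def fun(x):
            return self._fast.residuals(
                {**self._base_params, **pm.to_params(x)})

        res = least_squares(fun, x0, bounds=(pm.lo, pm.hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        p = pm.to_params(res.x)
        return SingleFit(params=p, x=np.asarray(res.x), cost=self.cost(p),
                         n_generations=0, seed=-1)

    def fit(
        self,
        n_runs: int = 400,
        seed: int = 0,
        ga_config: GAConfig | None = None,
        n_jobs: int = 1,
    ) -> EnsembleFitResult:
        """Ensemble of independent GA runs; see :func:`ensemble_fit`."""
        result = ensemble_fit(self.cost, self.param_specs, n_runs=n_runs,
                              base_seed=seed, ga_config=ga_config, n_jobs=n_jobs)
        result.model = self
        return result

    def predict(self, params: dict[str, float], dataset: ScatteringDataset):
        """Model intensity on a dataset's fitted window (scale/bg profiled)."""
        model = self.build(params)
        dsw = dataset.windowed()
        ff = form_factor_analytic(model, dataset.probe, dataset.x_D, dsw.q)
        y = ff.F**2 / dsw.q**2
        s, b = _profile_scale_background(
            y, dsw.I, 1.0 / dsw.sigma**2, dataset.scale, dataset.background)
        return dsw.q, s * y + b
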