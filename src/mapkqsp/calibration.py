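"""Parameter estimation and sensitivity analysis.

Signaling parameters are estimated by particle swarm optimization (PSO)
against pERK time-course and 72-h growth-phenotype objectives; drug-target
IC50s by pooled nonlinear least squares on viability dose–response curves;
in vivo proliferation/death/alternate-receptor parameters by least squares
on xenograft tumor-volume kinetics; and local parameter sensitivity
coefficients (LPSC) by +10% perturbations of each parameter.

Because most signaling parameters are not individually identifiable, PSO is
run repeatedly (default 20 runs) from different seeds and downstream
analyses work with the ensemble of best solutions rather than a single
point estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import _engine
from .core_model import SignalingParams, Genotype, apply_genotype

__all__ = [
    "pso_minimize", "FitSpec", "FitResult", "PerkDataset", "GrowthDataset",
    "CalibrationData", "pso_fit_signaling", "Ic50Fit", "fit_drug_ic50",
    "XenograftFit", "fit_xenograft_params", "local_sensitivity",
    "DEFAULT_BOUNDS",
]


# ---------------------------------------------------------------------------
# particle swarm optimizer (constriction form)


def pso_minimize(fun: Callable[[np.ndarray], np.ndarray],
                 lo: np.ndarray, hi: np.ndarray,
                 n_particles: int = 100, iters: int = 500, seed=0,
                 w: float = 0.729, c1: float = 1.49, c2: float = 1.49,
                 tol_stall: int | None = None,
                 init: np.ndarray | None = None) -> dict:
    """Minimize ``fun`` over the box [lo, hi].

    ``fun`` maps a position matrix (n_particles, d) to a cost vector
    (n_particles,).  Deterministic given ``seed``.  ``init`` optionally
    places the first rows of the swarm at given positions (e.g. survivors
    of a coarse random screen); the rest are drawn uniformly.  Returns a
    dict with ``x`` (best position), ``cost``, and the per-iteration
    ``trace`` of the best cost.
    """
    rng = np.random.default_rng(seed)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    d = lo.size
    x = rng.uniform(lo, hi, size=(n_particles, d))
    if init is not None:
        init = np.clip(np.atleast_2d(init), lo, hi)
        k = min(init.shape[0], n_particles)
        x[:k] = init[:k]
    v = np.zeros_like(x)
    cost = np.asarray(fun(x), float)
    pbest_x = x.copy()
    pbest_c = cost.copy()
    g = int(np.argmin(cost))
    gbest_x = x[g].copy()
    gbest_c = float(cost[g])
    trace = [gbest_c]
    stall = 0
    for _ in range(iters):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        v = w * v + c1 * r1 * (pbest_x - x) + c2 * r2 * (gbest_x - x)
        x = np.clip(x + v, lo, hi)
        cost = np.asarray(fun(x), float)
        improved = cost < pbest_c
        pbest_x[improved] = x[improved]
        pbest_c[improved] = cost[improved]
        g = int(np.argmin(pbest_c))
        if pbest_c[g] < gbest_c - 1e-15:
            gbest_c = float(pbest_c[g])
            gbest_x = pbest_x[g].copy()
            stall = 0
        else:
            stall += 1
        trace.append(gbest_c)
        if tol_stall is not None and stall >= tol_stall:
            break
    return {"x": gbest_x, "cost": gbest_c, "trace": np.asarray(trace)}


# ---------------------------------------------------------------------------
# fit specification / result containers


#: default search boxes; Hill half-maxes / gains searched on a log scale.
DEFAULT_BOUNDS: dict = {}
for _n in ("tau1", "tau2", "tau3", "tau4", "tau5", "tau6", "tau7", "tau8",
           "tauFB1", "tauFB2", "tauFB3", "tauFB4", "taug"):
    DEFAULT_BOUNDS[_n] = (1e-3, 10.0)
for _n in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8",
           "kFB1", "kFB2", "kFB3", "kFB4", "kg"):
    DEFAULT_BOUNDS[_n] = (0.5, 6.0)
for _n in ("r1", "r2", "r3", "r4", "r5"):
    DEFAULT_BOUNDS[_n] = (0.1, 20.0)
for _n in ("G13", "G23", "G33", "G34", "Gdusp", "Gspry"):
    DEFAULT_BOUNDS[_n] = (1e-3, 1.0)
for _n in ("muMAX", "deltaMAX"):
    DEFAULT_BOUNDS[_n] = (1e-3, 2.0)


@dataclass
class FitSpec:
    """Free parameters, bounds and optimizer settings for a PSO fit."""

    free: Sequence[str]
    bounds: Mapping[str, tuple] = field(default_factory=dict)
    log_scale: bool = True
    n_particles: int = 100
    iters: int = 5000
    n_runs: int = 20
    seed: int = 0
    mse_ceiling: float = np.inf

    def __post_init__(self):
        known = set(SignalingParams.names())
        for name in self.free:
            if name not in known:
                raise ValueError(f"unknown free parameter {name!r}")
        self.bounds = {**{n: DEFAULT_BOUNDS[n] for n in self.free
                          if n in DEFAULT_BOUNDS}, **dict(self.bounds)}
        for name in self.free:
            if name not in self.bounds:
                raise ValueError(f"no bounds for free parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: {(lo, hi)}")


@dataclass
class FitResult:
    """All per-run solutions (no silent discard), sorted by MSE."""

    table: pd.DataFrame          # columns: run, mse, <free params>, at_bounds
    traces: list
    spec: FitSpec
    converged: bool

    def best(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "mse")

    def parameter_sets(self, base: SignalingParams, k: int | None = None
                       ) -> list:
        rows = self.table if k is None else self.best(k)
        return [base.replace(**{n: float(row[n]) for n in self.spec.free})
                for _, row in rows.iterrows()]


def _boundary_flags(xs: Mapping[str, float], spec: FitSpec) -> str:
    hits = []
    for name in spec.free:
        lo, hi = spec.bounds[name]
        x = xs[name]
        if spec.log_scale and lo > 0:
            t = (np.log10(x) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        else:
            t = (x - lo) / (hi - lo)
        if t < 1e-3 or t > 1 - 1e-3:
            hits.append(name)
    return ",".join(hits)


# ---------------------------------------------------------------------------
# calibration datasets


@dataclass
class PerkDataset:
    """Normalized pERK time course under generic target suppression."""

    genotype: Genotype
    suppression: Mapping[str, float]
    t_h: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, float)
        self.values = np.asarray(self.values, float)
        if self.t_h.shape != self.values.shape:
            raise ValueError("time and value arrays differ in length")


@dataclass
class GrowthDataset:
    """Fold expansion of a culture under generic target suppression."""

    genotype: Genotype
    suppression: Mapping[str, float]
    fold: float
    duration_h: float = 72.0


@dataclass
class CalibrationData:
    perk: Sequence[PerkDataset] = ()
    growth: Sequence[GrowthDataset] = ()


def _condition_params(base: SignalingParams, genotypes: Sequence[Genotype],
                      free: Sequence[str], particles: np.ndarray) -> dict:
    """Stack condition (rows) × particle (cols) parameter arrays."""
    n_cond = len(genotypes)
    cols = {}
    per_cond = [apply_genotype(base, g).to_dict() for g in genotypes]
    for name in SignalingParams.names():
        vals = np.array([pc[name] for pc in per_cond])[:, None]
        cols[name] = vals
    for j, name in enumerate(free):
        cols[name] = np.broadcast_to(particles[None, :, j], (n_cond, particles.shape[0]))
    return cols


def _stack_suppression(datasets) -> dict:
    nodes = sorted({n for d in datasets for n in d.suppression})
    return {n: np.array([d.suppression.get(n, 0.0)
                         for d in datasets])[:, None] for n in nodes}


def signaling_objective(data: CalibrationData, base: SignalingParams,
                        free: Sequence[str], dt: float = 0.02) -> Callable:
    """Vectorized MSE objective over a particle position matrix.

    The pERK-dynamics and growth-phenotype objectives are weighted equally
    as groups (each group's MSE is the mean over its datasets); pERK values
    are already on the [0, 1] baseline-relative scale and fold expansions
    are compared on a relative scale.
    """
    perk = list(data.perk)
    growth = list(data.growth)

    def objective(particles: np.ndarray) -> np.ndarray:
        particles = np.atleast_2d(particles)
        n_part = particles.shape[0]
        group_mses = []
        mses = []
        if perk:
            p = _condition_params(base, [d.genotype for d in perk], free,
                                  particles)
            supp = _stack_suppression(perk)
            fb0, td10, nodes0 = _engine.equilibrate(p, days=15.0)
            baseline = np.maximum(nodes0["ERK"], 1e-9)
            t_end = max(d.t_h.max() for d in perk) / 24.0
            res = _engine.simulate(p, t_end, dt, fb0=fb0, td10=td10,
                                   suppression=supp, record_nodes=("ERK",))
            erk = res["ERK"] / baseline[None, :, :]
            tg = res["t"] * 24.0
            for i, d in enumerate(perk):
                idx = np.clip(d.t_h / (tg[1] - tg[0]), 0, tg.size - 1)
                i0 = np.floor(idx).astype(int)
                i1 = np.minimum(i0 + 1, tg.size - 1)
                frac = (idx - i0)[:, None]
                sim = erk[i0, i, :] * (1 - frac) + erk[i1, i, :] * frac
                mses.append(np.mean((sim - d.values[:, None]) ** 2, axis=0))
            group_mses.append(np.mean(np.stack(mses, axis=0), axis=0))
            mses = []
        if growth:
            p = _condition_params(base, [d.genotype for d in growth], free,
                                  particles)
            supp = _stack_suppression(growth)
            fb0, td10, _ = _engine.equilibrate(p, days=15.0)
            dur = growth[0].duration_h / 24.0
            res = _engine.simulate(p, dur, dt, fb0=fb0, td10=td10,
                                   suppression=supp, cells0=1.0)
            folds = res["cells"][-1]
            target = np.array([d.fold for d in growth])[:, None]
            rel = (folds - target) / np.maximum(np.abs(target), 1e-9)
            for i in range(len(growth)):
                mses.append(rel[i] ** 2)
            group_mses.append(np.mean(np.stack(mses, axis=0), axis=0))
        if not group_mses:
            return np.zeros(n_part)
        return np.mean(np.stack(group_mses, axis=0), axis=0)

    return objective


def pso_fit_signaling(spec: FitSpec, data: CalibrationData,
                      base: SignalingParams | None = None,
                      dt: float = 0.02) -> FitResult:
    """PSO estimation of signaling parameters against calibration data.

    Runs ``spec.n_runs`` independent swarms (seeds derived from
    ``spec.seed``) and returns every run's solution sorted by MSE; use
    ``FitResult.best(10)`` for the downstream solution ensemble.
    """
    base = base or SignalingParams()
    obj = signaling_objective(data, base, spec.free, dt=dt)
    free = list(spec.free)
    d = len(free)
    if d == 0:
        mse = float(obj(np.zeros((1, 0)))[0])
        table = pd.DataFrame([{"run": 0, "mse": mse, "at_bounds": ""}])
        return FitResult(table=table, traces=[np.array([mse])], spec=spec,
                         converged=mse <= spec.mse_ceiling)
    lo = np.array([spec.bounds[n][0] for n in free])
    hi = np.array([spec.bounds[n][1] for n in free])
    if spec.log_scale:
        if np.any(lo <= 0):
            raise ValueError("log-scale search requires positive bounds")
        slo, shi = np.log10(lo), np.log10(hi)
        decode = lambda z: 10.0 ** z
    else:
        slo, shi = lo, hi
        decode = lambda z: z

    rows = []
    traces = []
    for run in range(spec.n_runs):
        res = pso_minimize(lambda z: obj(decode(z)), slo, shi,
                           n_particles=spec.n_particles, iters=spec.iters,
                           seed=np.random.SeedSequence([spec.seed, run]))
        x = decode(res["x"])
        row = {"run": run, "mse": res["cost"]}
        row.update({n: x[j] for j, n in enumerate(free)})
        row["at_bounds"] = _boundary_flags(row, spec)
        rows.append(row)
        traces.append(res["trace"])
    table = pd.DataFrame(rows).sort_values("mse").reset_index(drop=True)
    converged = bool((table["mse"] <= spec.mse_ceiling).any())
    return FitResult(table=table, traces=traces, spec=spec,
                     converged=converged)


# ---------------------------------------------------------------------------
# drug-target IC50 estimation


@dataclass
class Ic50Fit:
    """Pooled drug-target inhibition estimate with per-line variability."""

    tau_i: float | None
    k_i: float | None
    status: str                     # "ok" | "not_estimable"
    cv_tau_pct: float | None = None
    per_line: pd.DataFrame | None = None
    at_bounds: str = ""
    residual_rms: float | None = None


def _viability_model(base: SignalingParams, target_node: str,
                     doses: np.ndarray, tau_i: float, k_i: float,
                     duration_h: float, dt: float) -> np.ndarray:
    tau_field = {"RTK1": "taui1", "BRAF": "taui2",
                 "MEK": "taui3", "ERK": "taui4"}[target_node]
    k_field = "ki" + tau_field[-1]
    p = {n: np.asarray(v, float) for n, v in base.to_dict().items()}
    p[tau_field] = float(tau_i)
    p[k_field] = float(k_i)
    grid = np.concatenate([[0.0], doses])
    fb0, td10, _ = _engine.equilibrate(p)
    res = _engine.simulate(p, duration_h / 24.0, dt, fb0=fb0, td10=td10,
                           const_conc={target_node: grid}, cells0=1.0)
    folds = res["cells"][-1]
    return folds[1:] / folds[0]


def fit_drug_ic50(curves: pd.DataFrame, target_node: str,
                  base: SignalingParams | None = None,
                  duration_h: float = 96.0, dt: float = 0.02,
                  flat_threshold: float = 0.05,
                  bounds_tau: tuple = (1e-5, 100.0),
                  bounds_k: tuple = (0.3, 6.0),
                  fix_k: float | None = None) -> Ic50Fit:
    """Least-squares estimate of a drug's target-inhibition (tau_i, k_i).

    ``curves`` needs columns ``cell_line``, ``dose`` (mg/L; a ``dose_molar``
    column is converted if ``mm`` is provided as an attr) and ``viability``
    (fraction of untreated).  Cell lines are pooled as replicates; per-line
    refits give the %CV.  Flat mean response declines estimation explicitly.

    When the viability transition spans only one or two dose levels, tau
    and k are jointly weakly identified (a steeper k with a larger tau fits
    equally well); ``fix_k`` pins the Hill coefficient when it is known by
    assay design, making tau sharply identified from the transition
    position.
    """
    base = base or SignalingParams()
    req = {"cell_line", "dose", "viability"}
    if not req <= set(curves.columns):
        raise ValueError(f"curves must have columns {sorted(req)}")
    doses = np.sort(curves["dose"].unique())
    if doses.size < 4:
        raise ValueError("need at least 4 dose levels")
    mean_resp = curves.groupby("dose")["viability"].mean()
    if mean_resp.max() - mean_resp.min() < flat_threshold:
        return Ic50Fit(tau_i=None, k_i=None, status="not_estimable")

    def fit_subset(sub: pd.DataFrame):
        dgrid = np.sort(sub["dose"].unique())
        obs = sub.groupby("dose")["viability"].mean().reindex(dgrid).to_numpy()

        def resid(z):
            k = fix_k if fix_k is not None else 10.0 ** z[1]
            sim = _viability_model(base, target_node, dgrid,
                                   10.0 ** z[0], k, duration_h, dt)
            return sim - obs

        if fix_k is not None:
            z0 = np.array([np.log10(np.median(dgrid))])
            sol = least_squares(resid, z0,
                                bounds=(np.log10([bounds_tau[0]]),
                                        np.log10([bounds_tau[1]])))
            return 10.0 ** sol.x[0], float(fix_k), sol
        z0 = np.array([np.log10(np.median(dgrid)), 0.0])
        sol = least_squares(
            resid, z0,
            bounds=(np.log10([bounds_tau[0], bounds_k[0]]),
                    np.log10([bounds_tau[1], bounds_k[1]])))
        return 10.0 ** sol.x[0], 10.0 ** sol.x[1], sol

    tau, k, sol = fit_subset(curves)
    per = []
    for line, sub in curves.groupby("cell_line"):
        try:
            tl, kl, _ = fit_subset(sub)
            per.append({"cell_line": line, "tau_i": tl, "k_i": kl})
        except Exception:
            per.append({"cell_line": line, "tau_i": np.nan, "k_i": np.nan})
    per = pd.DataFrame(per)
    cv = float(100.0 * per["tau_i"].std() / per["tau_i"].mean()) \
        if per["tau_i"].notna().sum() > 1 else None
    flags = []
    for val, (lo, hi), nm in ((tau, bounds_tau, "tau_i"), (k, bounds_k, "k_i")):
        t = (np.log10(val) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        if t < 1e-3 or t > 1 - 1e-3:
            flags.append(nm)
    return Ic50Fit(tau_i=tau, k_i=k, status="ok", cv_tau_pct=cv, per_line=per,
                   at_bounds=",".join(flags),
                   residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))))


# ---------------------------------------------------------------------------
# xenograft fitting


@dataclass
class XenograftFit:
    estimates: dict
    residual_rms: float
    r2: float
    at_bounds: str
    solution: object


def fit_xenograft_params(volumes: pd.DataFrame,
                         arm_exposures: Mapping[str, Mapping[str, np.ndarray]],
                         base: SignalingParams,
                         free: Sequence[str] = ("muMAX", "deltaMAX", "RTK2t"),
                         dt: float = 0.02,
                         vmax_fold: float = 10.0,
                         bounds: Mapping[str, tuple] | None = None
                         ) -> XenograftFit:
    """Least-squares fit of in vivo parameters to tumor-volume kinetics.

    ``volumes`` has columns ``arm``, ``day``, ``volume`` (replicates are
    averaged per arm × day); ``arm_exposures`` maps arm names to per-node
    concentration half-grids (mg/L at tumor) spanning the study duration
    with step ``dt``.  All signaling and IC50 parameters stay frozen at the
    in vitro values in ``base``; the carrying capacity is ``vmax_fold`` ×
    the mean baseline volume.
    """
    req = {"arm", "day", "volume"}
    if not req <= set(volumes.columns):
        raise ValueError(f"volumes must have columns {sorted(req)}")
    arms = [a for a in volumes["arm"].unique() if a in arm_exposures]
    missing = set(volumes["arm"].unique()) - set(arm_exposures)
    if missing:
        raise ValueError(f"no exposure defined for arm(s) {sorted(missing)}")
    if len(arms) < len(free):
        raise ValueError(
            f"{len(arms)} arms cannot determine {len(free)} parameters")
    mean_v = volumes.groupby(["arm", "day"])["volume"].mean().reset_index()
    v0 = float(mean_v[mean_v["day"] == mean_v["day"].min()]["volume"].mean())
    duration = float(mean_v["day"].max())
    bounds = dict(bounds or {})
    for name in free:
        bounds.setdefault(name, DEFAULT_BOUNDS.get(name, (1e-3, 10.0)))
    lo = np.log10([bounds[n][0] for n in free])
    hi = np.log10([bounds[n][1] for n in free])

    obs_by_arm = {a: mean_v[mean_v["arm"] == a].sort_values("day")
                  for a in arms}

    def resid(z):
        over = {n: 10.0 ** z[j] for j, n in enumerate(free)}
        p = {k: np.asarray(v, float)
             for k, v in base.replace(VMAX=vmax_fold * v0, **over
                                      ).to_dict().items()}
        fb0, td10, _ = _engine.equilibrate(p)
        out = []
        for a in arms:
            res = _engine.simulate(p, duration, dt, fb0=fb0, td10=td10,
                                   cells0=v0,
                                   conc_half_grid=arm_exposures[a] or None)
            obs = obs_by_arm[a]
            sim = np.interp(obs["day"].to_numpy(), res["t"], res["cells"])
            out.append((sim - obs["volume"].to_numpy()) / v0)
        return np.concatenate(out)

    z0 = np.log10([np.clip(getattr(base, n), bounds[n][0] * 1.01,
                           bounds[n][1] * 0.99) for n in free])
    sol = least_squares(resid, z0, bounds=(lo, hi))
    est = {n: float(10.0 ** sol.x[j]) for j, n in enumerate(free)}
    r = sol.fun
    obs_all = np.concatenate(
        [obs_by_arm[a]["volume"].to_numpy() for a in arms]) / v0
    ss_tot = float(np.sum((obs_all - obs_all.mean()) ** 2))
    r2 = 1.0 - float(np.sum(r ** 2)) / ss_tot if ss_tot > 0 else np.nan
    flags = [n for j, n in enumerate(free)
             if (sol.x[j] - lo[j]) / (hi[j] - lo[j]) < 1e-3
             or (sol.x[j] - lo[j]) / (hi[j] - lo[j]) > 1 - 1e-3]
    return XenograftFit(estimates=est,
                        residual_rms=float(np.sqrt(np.mean(r ** 2))),
                        r2=r2, at_bounds=",".join(flags), solution=sol)


# ---------------------------------------------------------------------------
# local parameter sensitivity


def local_sensitivity(param_sets: Sequence[SignalingParams],
                      treatments: Mapping[str, Mapping],
                      horizon: float = 21.0,
                      scan: Sequence[str] | None = None,
                      delta: float = 0.10,
                      dt: float = 0.02,
                      cells0: float = 1.0) -> pd.DataFrame:
    """LPSC = (ΔT/T)/(ΔP/P) for a +``delta`` perturbation of each parameter.

    ``treatments`` maps treatment names to exposure dicts with optional keys
    ``suppression`` (node → fraction) and ``conc`` (node → half-grid
    concentration array for ``horizon``/``dt``).  Edge rules: parameters at
    0 are raised to 0.1 (ΔP/P taken as 1); parameters at 1 are lowered to
    0.9 with the reference simulated at 0.99.  Values are averaged across
    the supplied parameter-set ensemble; simulation failures are flagged as
    NaN entries rather than silently zeroed.
    """
    scan = list(scan) if scan is not None else [
        n for n in SignalingParams.names()
        if n not in ("VMAX",)]
    out = np.zeros((len(scan), len(treatments)))
    counts = np.zeros_like(out)
    for base in param_sets:
        bd = base.to_dict()
        variants = []           # (scan_idx, dict, kind, dP_over_P, is_ref)
        rows = {}
        for i, name in enumerate(scan):
            v = bd[name]
            if v == 0.0:
                rows[i] = (dict(bd, **{name: 0.1}), None, 1.0)
            elif v == 1.0:
                rows[i] = (dict(bd, **{name: 0.9}),
                           dict(bd, **{name: 0.99}), (0.9 - 0.99) / 0.99)
            else:
                rows[i] = (dict(bd, **{name: v * (1 + delta)}), None, delta)
        stack = [bd]
        index_of = {}
        for i, (pert, ref, _) in rows.items():
            index_of[(i, "pert")] = len(stack)
            stack.append(pert)
            if ref is not None:
                index_of[(i, "ref")] = len(stack)
                stack.append(ref)
        p = {n: np.array([s[n] for s in stack]) for n in SignalingParams.names()}
        fb0, td10, _ = _engine.equilibrate(p)
        for j, (tname, exp) in enumerate(treatments.items()):
            try:
                res = _engine.simulate(
                    p, horizon, dt, fb0=fb0, td10=td10, cells0=cells0,
                    suppression=exp.get("suppression"),
                    conc_half_grid=exp.get("conc"))
                T = res["cells"][-1]
            except Exception:
                out[:, j] = np.nan
                continue
            for i, (_, ref, dpp) in rows.items():
                t_ref = T[index_of[(i, "ref")]] if (i, "ref") in index_of \
                    else T[0]
                lpsc = ((T[index_of[(i, "pert")]] - t_ref) / t_ref) / dpp
                out[i, j] += lpsc
                counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(counts > 0, out / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(avg, index=scan, columns=list(treatments))
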