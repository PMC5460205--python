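"""Drug pharmacokinetics: compartmental models, regimens, populations.

Four drugs are modeled: cetuximab (EGFR blocking antibody, IV
one-compartment), vemurafenib (BRAFi, oral two-compartment), cobimetinib
(MEKi, oral one-compartment) and GDC-0994 (ERKi, oral one-compartment), with
the published human population means, between-subject %CV, maximum tolerated
dose (MTD) regimens, drug-target IC50s and murine scaling factors.

All PK systems are linear, so trajectories are propagated exactly by matrix
exponentials between impulsive dose events; dose amounts are folded into the
``/F`` parameterization (bioavailability absorbed into V and CL).

Murine parameterizations apply the tabulated murine/human factors to the
body-weight-normalized parameters: ``Ka`` is multiplied by its factor, while
volumes and clearances are multiplied by factor × (body weight / 70 kg).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DrugModel", "Regimen", "PopulationPK", "DRUG_LIBRARY", "DRUG_BY_TARGET",
    "REGIMEN_TEMPLATES", "build_regimen", "regimen_from_file", "simulate_pk",
    "sample_population_pk", "tumor_exposure", "ensemble_concentration",
]

HUMAN_BW_KG = 70.0
MOUSE_BW_KG = 0.025  # average 24-26 g study animal

STRUCTURES = ("iv_1cmt", "oral_1cmt", "oral_2cmt")


@dataclass(frozen=True)
class DrugModel:
    """Per-drug PK structure, target-inhibition term, and partitioning.

    ``vc``/``cl``/``v2``/``q`` are apparent (/F) values in L and L/day;
    ``ka`` per day; ``ic50`` (``tau_i``) in mg/L with Hill coefficient
    ``hill_i``; ``partition`` is the tumor:blood partition fraction;
    ``cv`` maps parameter names to between-subject %CV; ``murine_scale``
    maps parameter names to the murine/human factor.
    """

    name: str
    target: str                 # cascade node: RTK1 | BRAF | MEK | ERK
    structure: str
    vc: float
    cl: float
    ka: float | None = None
    v2: float | None = None
    q: float | None = None
    ic50: float = 1.0
    hill_i: float = 1.0
    mm: float = 500.0           # molecular mass g/mol
    partition: float = 1.0
    cv: Mapping[str, float] = field(default_factory=dict)
    murine_scale: Mapping[str, float] = field(default_factory=dict)
    mtd_mg: float | None = None
    mtd_mg_per_kg_murine: float | None = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown PK structure {self.structure!r}")
        if self.vc <= 0 or self.cl <= 0:
            raise ValueError("volumes and clearances must be positive")
        if self.structure.startswith("oral") and not self.ka:
            raise ValueError("oral model requires Ka")
        if self.structure == "oral_2cmt" and (
                not self.v2 or self.q is None or self.q < 0):
            raise ValueError("two-compartment model requires V2 and Q >= 0")
        if not 0.0 < self.partition <= 1.0:
            raise ValueError("partition coefficient must lie in (0, 1]")

    def replace(self, **kw) -> "DrugModel":
        return dataclasses.replace(self, **kw)

    def for_species(self, species: str,
                    body_kg: float = MOUSE_BW_KG) -> "DrugModel":
        """Murine parameterization via the tabulated scale factors."""
        if species == "human":
            return self
        if species != "mouse":
            raise ValueError("species must be 'human' or 'mouse'")
        s = dict(self.murine_scale)
        bw = body_kg / HUMAN_BW_KG
        kw: dict = {"vc": self.vc * s.get("vc", 1.0) * bw,
                    "cl": self.cl * s.get("cl", 1.0) * bw}
        if self.ka is not None:
            kw["ka"] = self.ka * s.get("ka", 1.0)
        if self.v2 is not None:
            kw["v2"] = self.v2 * s.get("v2", 1.0) * bw
        if self.q is not None:
            kw["q"] = self.q * s.get("q", 1.0) * bw
        return self.replace(**kw)

    # -- linear system ------------------------------------------------------

    def matrix(self) -> tuple:
        """(M, dose_index, central_index) of the amount-space linear system."""
        ke = self.cl / self.vc
        if self.structure == "iv_1cmt":
            return np.array([[-ke]]), 0, 0
        if self.structure == "oral_1cmt":
            return np.array([[-self.ka, 0.0], [self.ka, -ke]]), 0, 1
        k12 = self.q / self.vc
        k21 = self.q / self.v2
        M = np.array([[-self.ka, 0.0, 0.0],
                      [self.ka, -(ke + k12), k21],
                      [0.0, k12, -k21]])
        return M, 0, 1


#: published drug models (human population means; %CV; murine/human factors).
DRUG_LIBRARY: dict = {
    "cetuximab": DrugModel(
        name="cetuximab", target="RTK1", structure="iv_1cmt",
        vc=4.5, cl=0.67, ic50=0.03, mm=152000.0,
        mtd_mg=450.0, mtd_mg_per_kg_murine=12.5),
    "vemurafenib": DrugModel(
        name="vemurafenib", target="BRAF", structure="oral_2cmt",
        ka=4.5, vc=114.0, cl=32.0, v2=335.0, q=252.0,
        ic50=0.027, mm=489.0,
        cv={"ka": 101.0, "vc": 68.0, "cl": 33.0, "v2": 75.0, "q": 72.0},
        murine_scale={"ka": 5.3, "vc": 0.61, "cl": 48.0, "v2": 1.0, "q": 1.0},
        mtd_mg=960.0, mtd_mg_per_kg_murine=50.0),
    "cobimetinib": DrugModel(
        name="cobimetinib", target="MEK", structure="oral_1cmt",
        ka=33.0, vc=487.0, cl=327.0, ic50=0.0032, mm=531.0,
        cv={"ka": 167.0, "vc": 51.0, "cl": 59.0},
        murine_scale={"ka": 0.7, "vc": 5.8, "cl": 15.9},
        mtd_mg=60.0, mtd_mg_per_kg_murine=5.0),
    "gdc0994": DrugModel(
        name="gdc0994", target="ERK", structure="oral_1cmt",
        ka=35.0, vc=171.0, cl=161.0, ic50=0.13, mm=441.0,
        cv={"ka": 173.0, "vc": 39.0, "cl": 43.0},
        murine_scale={"ka": 0.19, "vc": 0.07, "cl": 13.1},
        mtd_mg=400.0, mtd_mg_per_kg_murine=50.0),
}

DRUG_BY_TARGET = {d.target: d for d in DRUG_LIBRARY.values()}


@dataclass(frozen=True)
class Regimen:
    """Dosing schedule: amount every ``interval_h`` hours during on-days of a
    ``days_on``/``days_off`` cycle (``days_off=0`` means continuous), for
    ``duration_d`` days starting at day 0."""

    drug: str
    amount: float               # mg, or mg/kg if per_kg
    interval_h: float
    duration_d: float
    days_on: float = 0.0        # 0 with days_off=0 -> continuous
    days_off: float = 0.0
    per_kg: bool = False
    route: str = "oral"

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose must be positive")
        if self.interval_h <= 0 or self.duration_d <= 0:
            raise ValueError("interval and duration must be positive")

    def events(self, body_kg: float | None = None) -> list:
        """Explicit (time_days, amount_mg) dose events."""
        amt = self.amount
        if self.per_kg:
            if body_kg is None:
                raise ValueError("per-kg regimen requires a body mass")
            amt = self.amount * body_kg
        dt = self.interval_h / 24.0
        cycle = self.days_on + self.days_off
        out = []
        t = 0.0
        eps = 1e-9
        while t < self.duration_d - eps:
            if cycle <= 0 or (t % cycle) < self.days_on - eps:
                out.append((round(t, 9), amt))
            t += dt
        return out


REGIMEN_TEMPLATES: dict = {
    # human single-agent MTD regimens
    "cetuximab": dict(drug="cetuximab", amount=450.0, interval_h=168.0,
                      route="iv"),
    "vemurafenib": dict(drug="vemurafenib", amount=960.0, interval_h=12.0),
    "cobimetinib": dict(drug="cobimetinib", amount=60.0, interval_h=24.0,
                        days_on=21.0, days_off=7.0),
    "gdc0994": dict(drug="gdc0994", amount=400.0, interval_h=24.0,
                    days_on=21.0, days_off=7.0),
    # murine MTD regimens (continuous dosing in 21-day xenograft studies)
    "cetuximab_murine": dict(drug="cetuximab", amount=12.5, interval_h=168.0,
                             per_kg=True, route="iv"),
    "vemurafenib_murine": dict(drug="vemurafenib", amount=50.0, interval_h=24.0,
                               per_kg=True),
    "cobimetinib_murine": dict(drug="cobimetinib", amount=5.0, interval_h=24.0,
                               per_kg=True),
    "gdc0994_murine": dict(drug="gdc0994", amount=50.0, interval_h=24.0,
                           per_kg=True),
}


def regimen_from_file(path) -> Regimen:
    """Load a regimen from a YAML or JSON mapping of Regimen fields."""
    import json
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return Regimen(**d)


def build_regimen(template: str, duration_d: float, **overrides) -> Regimen:
    """Instantiate a named MTD regimen template over ``duration_d`` days."""
    if template not in REGIMEN_TEMPLATES:
        raise KeyError(f"unknown regimen template {template!r}; "
                       f"known: {sorted(REGIMEN_TEMPLATES)}")
    kw = dict(REGIMEN_TEMPLATES[template])
    kw.update(overrides)
    return Regimen(duration_d=duration_d, **kw)


# ---------------------------------------------------------------------------
# simulation


def _propagate(M: np.ndarray, s0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """States at relative times ``dts`` from ``s0`` under ``x' = M x``."""
    w, P = np.linalg.eig(M)
    try:
        coef = np.linalg.solve(P, s0.astype(complex))
        cond_ok = np.linalg.cond(P) < 1e10
    except np.linalg.LinAlgError:
        cond_ok = False
    if cond_ok:
        out = np.real(np.einsum("ij,tj->ti", P, np.exp(np.outer(dts, w)) * coef))
        return out
    return np.array([expm(M * dt) @ s0 for dt in dts])


def simulate_pk(d: DrugModel, r: Regimen,
                t_span: tuple = None,
                t_eval: np.ndarray | None = None,
                body_kg: float | None = None,
                return_amounts: bool = False):
    """Blood concentration trajectory (mg/L) under a dosing regimen.

    Exact piecewise propagation of the linear compartment system with
    impulsive dosing (gut for oral, central for IV).  With
    ``return_amounts=True`` also returns per-compartment amounts and the
    cumulative eliminated amount, integrated by augmenting the system with
    an elimination accumulator.
    """
    if r.drug != d.name:
        raise ValueError(f"regimen drug {r.drug!r} does not match model {d.name!r}")
    if t_span is None:
        t_span = (0.0, r.duration_d)
    events = r.events(body_kg=body_kg)
    kept = [(t, a) for t, a in events if t_span[0] <= t <= t_span[1]]
    if len(kept) != len(events):
        warnings.warn("dose events outside t_span were clipped")
    M, dose_idx, central_idx = d.matrix()
    m = M.shape[0]
    # augment with elimination accumulator: d(elim)/dt = ke * central
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = M
    A[m, central_idx] = d.cl / d.vc
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 501)
    t_eval = np.asarray(t_eval, dtype=float)
    state = np.zeros(m + 1)
    out = np.zeros((t_eval.size, m + 1))
    times = sorted(set([t for t, _ in kept]) | {t_span[0]})
    bounds = times + [np.inf]
    for i, t0 in enumerate(times):
        for te, amt in kept:
            if te == t0:
                state[dose_idx] += amt
        t1 = bounds[i + 1]
        mask = (t_eval >= t0) & (t_eval < t1) if np.isfinite(t1) \
            else (t_eval >= t0)
        if mask.any():
            out[mask] = _propagate(A, state, t_eval[mask] - t0)
        if np.isfinite(t1):
            state = _propagate(A, state, np.array([t1 - t0]))[0]
    conc = out[:, central_idx] / d.vc
    # eigen-propagation can leave O(1e-16) negative round-off at dose times
    conc[np.abs(conc) < 1e-12] = np.abs(conc[np.abs(conc) < 1e-12])
    if return_amounts:
        return t_eval, conc, out[:, :m], out[:, m]
    return t_eval, conc


# ---------------------------------------------------------------------------
# population PK


@dataclass(frozen=True)
class PopulationPK:
    """Log-normal population model: P_i = THETA_i * exp(ETA_i) with
    ETA ~ MVN(0, OMEGA) on the natural-log scale."""

    theta: Mapping[str, float]
    omega: np.ndarray           # covariance, ordered as theta keys

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (len(self.theta), len(self.theta)):
            raise ValueError("OMEGA shape does not match THETA")
        if not np.allclose(om, om.T):
            raise ValueError("OMEGA must be symmetric")
        if np.min(np.linalg.eigvalsh(om)) < -1e-10:
            raise ValueError("OMEGA must be positive semi-definite")

    @classmethod
    def from_drug(cls, d: DrugModel) -> "PopulationPK":
        """Diagonal OMEGA from the tabulated between-subject %CV."""
        names = [n for n in ("ka", "vc", "cl", "v2", "q")
                 if getattr(d, n) is not None]
        theta = {n: float(getattr(d, n)) for n in names}
        var = [np.log(1.0 + (d.cv.get(n, 0.0) / 100.0) ** 2) for n in names]
        return cls(theta=theta, omega=np.diag(var))

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"theta": dict(self.theta),
                       "omega": np.asarray(self.omega).tolist()}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path) -> "PopulationPK":
        import json
        with open(path) as fh:
            d = json.load(fh)
        return cls(theta=d["theta"], omega=np.asarray(d["omega"]))

    def sample(self, n: int, seed) -> dict:
        """Deterministic dict of parameter arrays, each shape (n,)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        names = list(self.theta)
        eta = rng.multivariate_normal(
            np.zeros(len(names)), np.asarray(self.omega, float), size=n,
            method="cholesky" if np.all(np.linalg.eigvalsh(
                np.asarray(self.omega)) > 1e-12) else "svd")
        return {name: self.theta[name] * np.exp(eta[:, j])
                for j, name in enumerate(names)}


def sample_population_pk(pop: PopulationPK, n: int, seed) -> list:
    """n parameter draws as dicts (combine with DrugModel.replace)."""
    cols = pop.sample(n, seed)
    names = list(cols)
    return [{k: float(cols[k][i]) for k in names} for i in range(n)]


def tumor_exposure(blood_conc, p: float):
    """Local (tumor) concentration = partition fraction × blood."""
    if not 0.0 < p <= 1.0:
        raise ValueError("partition coefficient must lie in (0, 1]")
    return np.asarray(blood_conc, dtype=float) * p


# ---------------------------------------------------------------------------
# ensemble concentration grids (for the vectorized cohort engine)


def ensemble_concentration(d: DrugModel, r: Regimen,
                           duration: float, dt: float,
                           subject_params: Mapping[str, np.ndarray] | None = None,
                           body_kg: float | None = None,
                           partition: float | None = None) -> np.ndarray:
    """Local tumor concentrations on the RK4 half-step grid.

    Returns shape ``(2*n_steps + 1,)`` for a single typical subject or
    ``(2*n_steps + 1, n)`` when ``subject_params`` holds per-subject PK
    parameter arrays.  Dose times must align with the half-step grid.
    """
    n_steps = int(round(duration / dt))
    dth = dt / 2.0
    n_half = 2 * n_steps + 1
    events = [(t, a) for t, a in r.events(body_kg=body_kg) if t <= duration]
    part = d.partition if partition is None else partition
    if not 0.0 < part <= 1.0:
        raise ValueError("partition coefficient must lie in (0, 1]")

    if subject_params is None:
        models = [d]
    else:
        n = len(next(iter(subject_params.values())))
        models = [d.replace(**{k: float(v[i]) for k, v in subject_params.items()})
                  for i in range(n)]
    m0, dose_idx, central_idx = models[0].matrix()
    m = m0.shape[0]
    n_sub = len(models)
    E = np.empty((n_sub, m, m))
    vc = np.empty(n_sub)
    for i, mod in enumerate(models):
        Mi, _, _ = mod.matrix()
        E[i] = expm(Mi * dth)
        vc[i] = mod.vc
    dose_at = {}
    for t, a in events:
        ih = int(round(t / dth))
        if abs(ih * dth - t) > 1e-6:
            raise ValueError(f"dose time {t} does not align with grid step {dth}")
        dose_at[ih] = dose_at.get(ih, 0.0) + a
    states = np.zeros((n_sub, m))
    out = np.empty((n_half, n_sub))
    for h in range(n_half):
        amt = dose_at.get(h)
        if amt is not None:
            states[:, dose_idx] += amt
        out[h] = states[:, central_idx] / vc
        if h < n_half - 1:
            states = np.einsum("nij,nj->ni", E, states)
    out *= part
    if subject_params is None:
        return out[:, 0]
    return out
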