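"""Quasi-steady-state MAPK signaling network coupled to logistic tumor growth.

The signal-transduction cascade (EGFR/RTK1, RTK2, RTK3, RAS, BRAF, CRAF, MEK,
ERK, PI3K, AKT, S6) is represented by algebraic Hill activation functions that
are re-evaluated at every integrator step; slow processes — the four
ERK/AKT-driven negative-feedback circuits (DUSP, SPRY, MYC, FOXO), the
signaling-to-growth delay, and cell number — are ordinary differential
equations.  Dynamic states are ``FB1..FB4`` (feedback transit compartments),
``TD1`` (growth delay) and ``CELLS`` (tumor size, logistic growth with
carrying capacity ``VMAX``).

Drug action enters each cognate node (RTK1i → RTK1, BRAFi → BRAF, MEKi → MEK,
ERKi → ERK) as a multiplicative ``1 − Hill(concentration)`` factor on the
whole node activity, so a V600E-mutant BRAF (basal activity 0.9) is still
druggable.  A "generic inhibitor" exposure mode multiplies the node by a
constant ``1 − suppression`` instead of a concentration-dependent factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SignalingParams",
    "Genotype",
    "NetworkState",
    "Trajectory",
    "DRUG_NODES",
    "GENOTYPE_OVERRIDES",
    "evaluate_cascade",
    "apply_genotype",
    "cascade_arrays",
    "state_derivatives",
    "simulate_system",
    "equilibrate",
    "simulate_perk_timecourse",
    "simulate_invitro_growth",
    "NoDrug",
    "TargetSuppression",
    "ConstantConcentration",
    "GriddedExposure",
]

#: cascade nodes in their evaluation order (CRAF is computed from RAS before
#: MEK because MEK consumes BRAF+CRAF; this is the only topologically
#: consistent ordering of the cascade).
NODE_ORDER = (
    "RTK1", "RTK2", "RTK3", "RAS", "CRAF", "BRAF",
    "MEK", "ERK", "PI3K", "AKT", "S6",
)

#: druggable nodes, in the order RTK1i/BRAFi/MEKi/ERKi.
DRUG_NODES = ("RTK1", "BRAF", "MEK", "ERK")


def hill(x, tau, k):
    """Hill activation ``x^k / (tau^k + x^k)``, safe for array input."""
    xr = np.maximum(np.asarray(x, dtype=float), 0.0) / tau
    xk = np.power(xr, k)
    return xk / (1.0 + xk)


@dataclass(frozen=True)
class SignalingParams:
    """Complete parameter set of the signaling + growth model.

    Node activities are dimensionless, bounded by basal (``*b``) and maximal
    (``*t``) values; rates ``r1..r5``, ``muMAX`` and ``deltaMAX`` are per day;
    drug half-maxes ``taui1..taui4`` are mg/L; ``VMAX`` is in the units of
    ``CELLS`` (cell number in vitro, tumor volume in vivo).
    """

    # node basal / maximal activities
    RTK1b: float = 0.0
    RTK1t: float = 1.0
    RTK2b: float = 0.0
    RTK2t: float = 0.1
    RTK3b: float = 0.0
    RTK3t: float = 0.1
    RASb: float = 0.05
    RASt: float = 1.0
    BRAFb: float = 0.0
    BRAFt: float = 1.0
    CRAFb: float = 0.0
    CRAFt: float = 1.0
    MEKb: float = 0.01
    MEKt: float = 1.0
    ERKb: float = 0.0
    ERKt: float = 1.0
    PI3Kb: float = 0.05
    PI3Kt: float = 1.0
    AKTb: float = 0.0
    AKTt: float = 1.0
    S6b: float = 0.0
    S6t: float = 1.0
    # cascade Hill half-maxes and coefficients
    tau1: float = 0.6
    tau2: float = 0.4
    tau3: float = 1.2
    tau4: float = 0.11
    tau5: float = 0.5
    tau6: float = 0.4
    tau7: float = 0.5
    tau8: float = 0.5
    k1: float = 3.0
    k2: float = 2.0
    k3: float = 2.0
    k4: float = 2.0
    k5: float = 2.0
    k6: float = 2.0
    k7: float = 2.0
    k8: float = 2.0
    # feedback gains
    G13: float = 0.5
    G23: float = 0.5
    G33: float = 0.5
    G34: float = 0.5
    Gdusp: float = 0.5
    Gspry: float = 0.5
    # feedback Hill half-maxes / coefficients
    tauFB1: float = 0.5
    tauFB2: float = 0.5
    tauFB3: float = 0.5
    tauFB4: float = 0.5
    kFB1: float = 2.0
    kFB2: float = 2.0
    kFB3: float = 2.0
    kFB4: float = 2.0
    # feedback / delay first-order rates (per day)
    r1: float = 2.0
    r2: float = 2.0
    r3: float = 1.0
    r4: float = 1.0
    r5: float = 1.0
    # pathway weights
    wOR: float = 1.0
    wRAS: float = 0.9
    # drug-target inhibition half-maxes (mg/L) and Hill coefficients
    taui1: float = 0.03
    taui2: float = 0.027
    taui3: float = 0.0032
    taui4: float = 0.13
    ki1: float = 1.0
    ki2: float = 1.0
    ki3: float = 1.0
    ki4: float = 1.0
    # growth
    muMAX: float = 0.7
    deltaMAX: float = 0.04
    taug: float = 0.3
    kg: float = 2.0
    VMAX: float = 1.0e6

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        d = self.to_dict()
        for node in ("RTK1", "RTK2", "RTK3", "RAS", "BRAF", "CRAF", "MEK",
                     "ERK", "PI3K", "AKT", "S6"):
            b, t = d[node + "b"], d[node + "t"]
            if b < 0 or b > t:
                raise ValueError(f"require 0 <= {node}b <= {node}t, got {b} > {t}")
        for name, v in d.items():
            if name.startswith(("tau", "k", "r")) or name in (
                    "muMAX", "deltaMAX", "VMAX"):
                if name != "deltaMAX" and v <= 0:
                    raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.deltaMAX < 0:
            raise ValueError("deltaMAX must be nonnegative")
        for w in ("wOR", "wRAS"):
            if not 0.0 <= d[w] <= 1.0:
                raise ValueError(f"{w} must lie in [0, 1], got {d[w]}")
        for g in ("G13", "G23", "G33", "G34", "Gdusp", "Gspry"):
            if d[g] < 0:
                raise ValueError(f"{g} must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "SignalingParams":
        unknown = set(overrides) - set(self.to_dict())
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "SignalingParams":
        return cls(**dict(d))

    @classmethod
    def names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignalingParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        """Flat key→value table."""
        with open(path, "w") as fh:
            fh.write("parameter,value\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k},{v!r}\n")

    @classmethod
    def from_csv(cls, path) -> "SignalingParams":
        import csv
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        return cls.from_dict({r["parameter"]: float(r["value"])
                              for r in rows})


#: named genotype / context flags mapped onto parameter overrides.
GENOTYPE_OVERRIDES: dict = {
    "BRAF_V600E": {"BRAFb": 0.9},
    "KRAS_mut": {"RASb": 0.9},
    "MEK_mut": {"MEKb": 0.9},
    "BRAF_amp": {"BRAFt": 5.0},
    "KRAS_amp": {"RASt": 5.0},
    "MEK_amp": {"MEKt": 5.0},
}

#: tissue context sets maximal EGFR expression/activity.
TISSUE_OVERRIDES = {"melanoma": {"RTK1t": 0.1}, "CRC": {"RTK1t": 1.0}}


@dataclass(frozen=True)
class Genotype:
    """Named mutation / expression context for a tumor model.

    ``mutations`` are keys of :data:`GENOTYPE_OVERRIDES`; ``tissue`` is
    ``"melanoma"`` (EGFR-low), ``"CRC"`` (EGFR-high) or ``None`` (leave
    RTK1t untouched); ``overrides`` are arbitrary extra parameter values
    applied last.
    """

    mutations: tuple = ()
    tissue: str | None = None
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        known = set(GENOTYPE_OVERRIDES)
        for m in self.mutations:
            if m not in known:
                raise ValueError(
                    f"unknown genotype {m!r}; known genotypes: {sorted(known)}")
        if self.tissue is not None and self.tissue not in TISSUE_OVERRIDES:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; known: {sorted(TISSUE_OVERRIDES)}")


def apply_genotype(base: SignalingParams, g: Genotype) -> SignalingParams:
    """Return a copy of ``base`` with the genotype's overrides applied."""
    changes: dict = {}
    for m in g.mutations:
        changes.update(GENOTYPE_OVERRIDES[m])
    if g.tissue is not None:
        changes.update(TISSUE_OVERRIDES[g.tissue])
    changes.update(g.overrides)
    return base.replace(**changes) if changes else base


# ---------------------------------------------------------------------------
# algebraic cascade


def cascade_arrays(p: Mapping[str, float | np.ndarray],
                   fb1, fb2, fb3, fb4,
                   conc: Mapping[str, float | np.ndarray] | None = None,
                   suppression: Mapping[str, float | np.ndarray] | None = None,
                   ) -> dict:
    """Evaluate all node activities; broadcasts over array-valued inputs.

    ``p`` maps parameter names (as in :class:`SignalingParams`) to scalars or
    arrays; ``conc`` maps druggable node names to local drug concentrations
    (mg/L); ``suppression`` maps node names to constant fractional target
    suppression (generic-inhibitor mode).  Both exposure modes compose.
    """
    conc = conc or {}
    suppression = suppression or {}

    def drug_factor(node: str, taui, ki):
        f = 1.0
        c = conc.get(node)
        if c is not None:
            f = f * (1.0 - hill(c, taui, ki))
        s = suppression.get(node)
        if s is not None:
            f = f * (1.0 - s)
        return f

    hfb3 = hill(fb3, p["tauFB3"], p["kFB3"])
    rtk1 = (p["RTK1b"] + (p["RTK1t"] - p["RTK1b"]) * (1.0 - p["G13"] * hfb3)) \
        * drug_factor("RTK1", p["taui1"], p["ki1"])
    rtk2 = p["RTK2b"] + (p["RTK2t"] - p["RTK2b"]) * (1.0 - p["G23"] * hfb3)
    rtk3 = p["RTK3b"] + (p["RTK3t"] - p["RTK3b"]) * (1.0 - p["G33"] * hfb3) \
        * (1.0 - p["G34"] * hill(fb4, p["tauFB4"], p["kFB4"]))
    ras = p["RASb"] + (p["RASt"] - p["RASb"]) \
        * hill(rtk1 + rtk2, p["tau1"], p["k1"]) \
        * (1.0 - p["Gspry"] * hill(fb2, p["tauFB2"], p["kFB2"]))
    craf = p["CRAFb"] + (p["CRAFt"] - p["CRAFb"]) * hill(ras, p["tau5"], p["k5"])
    braf = (p["BRAFb"] + (p["BRAFt"] - p["BRAFb"]) * hill(ras, p["tau2"], p["k2"])) \
        * drug_factor("BRAF", p["taui2"], p["ki2"])
    mek = (p["MEKb"] + (p["MEKt"] - p["MEKb"])
           * hill(braf + craf, p["tau3"], p["k3"])) \
        * drug_factor("MEK", p["taui3"], p["ki3"])
    erk = (p["ERKb"] + (p["ERKt"] - p["ERKb"]) * hill(mek, p["tau4"], p["k4"])
           * (1.0 - p["Gdusp"] * hill(fb1, p["tauFB1"], p["kFB1"]))) \
        * drug_factor("ERK", p["taui4"], p["ki4"])
    pi3k = p["PI3Kb"] + (p["PI3Kt"] - p["PI3Kb"]) \
        * hill(p["wRAS"] * ras + rtk3, p["tau7"], p["k7"])
    akt = p["AKTb"] + (p["AKTt"] - p["AKTb"]) * hill(pi3k, p["tau8"], p["k8"])
    s6 = p["S6b"] + (p["S6t"] - p["S6b"]) * hill(
        p["wOR"] * erk + (1.0 - p["wOR"]) * akt, p["tau6"], p["k6"])
    return {"RTK1": rtk1, "RTK2": rtk2, "RTK3": rtk3, "RAS": ras,
            "CRAF": craf, "BRAF": braf, "MEK": mek, "ERK": erk,
            "PI3K": pi3k, "AKT": akt, "S6": s6}


def evaluate_cascade(params: SignalingParams,
                     local_drug_conc: Mapping[str, float] | None = None,
                     feedback_state: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
                     suppression: Mapping[str, float] | None = None) -> dict:
    """Node activities for given feedback state and local drug exposure.

    ``local_drug_conc`` maps target node names (``RTK1``, ``BRAF``, ``MEK``,
    ``ERK``) to concentrations in mg/L.
    """
    if local_drug_conc:
        unknown = set(local_drug_conc) - set(DRUG_NODES)
        if unknown:
            raise ValueError(f"unknown drug target node(s): {sorted(unknown)}")
        for node, c in local_drug_conc.items():
            if c < 0:
                raise ValueError(f"negative concentration for {node}: {c}")
    if suppression:
        for node, s in suppression.items():
            if not 0.0 <= s < 1.0:
                raise ValueError(f"suppression for {node} must be in [0,1): {s}")
    fb1, fb2, fb3, fb4 = feedback_state
    return cascade_arrays(params.to_dict(), fb1, fb2, fb3, fb4,
                          conc=local_drug_conc, suppression=suppression)


def state_derivatives(p: Mapping[str, float | np.ndarray],
                      fb1, fb2, fb3, fb4, td1, cells, nodes: Mapping) -> tuple:
    """Time derivatives of the six dynamic states given node activities."""
    dfb1 = p["r1"] * (nodes["ERK"] - fb1)
    dfb2 = p["r2"] * (nodes["ERK"] - fb2)
    dfb3 = p["r3"] * (nodes["ERK"] - fb3)
    dfb4 = p["r4"] * (nodes["AKT"] - fb4)
    dtd1 = p["r5"] * (nodes["S6"] - td1)
    growth = p["muMAX"] * hill(td1, p["taug"], p["kg"]) - p["deltaMAX"]
    dcells = growth * (1.0 - cells / p["VMAX"]) * cells
    return dfb1, dfb2, dfb3, dfb4, dtd1, dcells


# ---------------------------------------------------------------------------
# exposure models


class NoDrug:
    """Drug-free exposure."""

    def concentrations(self, t):
        return None

    suppression = None


class TargetSuppression:
    """Generic-inhibitor mode: constant fractional suppression per node."""

    def __init__(self, suppression: Mapping[str, float]):
        for node, s in suppression.items():
            if node not in DRUG_NODES:
                raise ValueError(f"unknown target node {node!r}")
            if not 0.0 <= s < 1.0:
                raise ValueError(f"suppression must be in [0,1), got {s}")
        self.suppression = dict(suppression)

    def concentrations(self, t):
        return None


class ConstantConcentration:
    """Constant local drug concentrations (mg/L), e.g. in vitro dosing."""

    suppression = None

    def __init__(self, conc: Mapping[str, float]):
        for node, c in conc.items():
            if node not in DRUG_NODES:
                raise ValueError(f"unknown target node {node!r}")
            if c < 0:
                raise ValueError(f"negative concentration for {node}: {c}")
        self._conc = dict(conc)

    def concentrations(self, t):
        return self._conc


class GriddedExposure:
    """Time-varying local concentrations interpolated from a dense grid."""

    suppression = None

    def __init__(self, t_grid: np.ndarray, conc: Mapping[str, np.ndarray]):
        self.t_grid = np.asarray(t_grid, dtype=float)
        self._conc = {k: np.asarray(v, dtype=float) for k, v in conc.items()}
        for node, v in self._conc.items():
            if node not in DRUG_NODES:
                raise ValueError(f"unknown target node {node!r}")
            if v.shape != self.t_grid.shape:
                raise ValueError("concentration grid shape mismatch")

    def concentrations(self, t):
        return {node: np.interp(t, self.t_grid, v)
                for node, v in self._conc.items()}


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class NetworkState:
    """Snapshot of the dynamic states plus derived node activities."""

    fb: np.ndarray          # (4,) FB1..FB4
    td1: float
    cells: float
    time: float = 0.0
    nodes: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Dense simulation output; node activities recomputed on the grid."""

    t: np.ndarray           # days
    fb: np.ndarray          # (n, 4)
    td1: np.ndarray
    cells: np.ndarray
    nodes: dict             # name -> (n,)

    def final_state(self) -> NetworkState:
        return NetworkState(fb=self.fb[-1].copy(), td1=float(self.td1[-1]),
                            cells=float(self.cells[-1]), time=float(self.t[-1]),
                            nodes={k: float(v[-1]) for k, v in self.nodes.items()})

    def to_frame(self):
        import pandas as pd
        recs = {"time": self.t, "TD1": self.td1, "CELLS": self.cells}
        for j in range(4):
            recs[f"FB{j + 1}"] = self.fb[:, j]
        recs.update(self.nodes)
        return pd.DataFrame(recs).melt(
            id_vars="time", var_name="state", value_name="value")


def simulate_system(params: SignalingParams,
                    exposure=None,
                    t_span: tuple = (0.0, 21.0),
                    initial_state: NetworkState | None = None,
                    t_eval: np.ndarray | None = None,
                    rtol: float = 1e-6,
                    atol: float = 1e-9) -> Trajectory:
    """Integrate the feedback/delay/growth ODEs with the algebraic cascade
    re-evaluated inside the right-hand side (LSODA).

    ``exposure`` is drug-free when ``None``; otherwise one of the exposure
    classes in this module (or anything with ``concentrations(t)`` and a
    ``suppression`` attribute).  Time is in days.
    """
    exposure = exposure or NoDrug()
    if initial_state is None:
        initial_state = NetworkState(fb=np.zeros(4), td1=0.0, cells=1.0)
    if initial_state.cells <= 0:
        raise ValueError("initial CELLS must be positive")
    pd_ = params.to_dict()
    supp = exposure.suppression

    def rhs(t, y):
        fb1, fb2, fb3, fb4, td1, cells = y
        nodes = cascade_arrays(pd_, fb1, fb2, fb3, fb4,
                               conc=exposure.concentrations(t),
                               suppression=supp)
        return state_derivatives(pd_, fb1, fb2, fb3, fb4, td1, cells, nodes)

    y0 = np.concatenate([initial_state.fb,
                         [initial_state.td1, initial_state.cells]])
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 241)
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"integrator failed at t={sol.t[-1] if sol.t.size else t_span[0]}: "
            f"{sol.message}; last state={sol.y[:, -1] if sol.t.size else y0}")
    fb = sol.y[:4].T
    td1 = sol.y[4]
    cells = sol.y[5]
    nodes = {}
    for name in NODE_ORDER:
        nodes[name] = np.empty_like(sol.t)
    for i, ti in enumerate(sol.t):
        ni = cascade_arrays(pd_, *fb[i], conc=exposure.concentrations(ti),
                            suppression=supp)
        for name in NODE_ORDER:
            nodes[name][i] = ni[name]
    return Trajectory(t=sol.t, fb=fb, td1=td1, cells=cells, nodes=nodes)


def equilibrate(params: SignalingParams, days: float = 30.0,
                cells0: float = 1.0) -> NetworkState:
    """Drug-free pre-equilibration: simulate ``days`` without drug and return
    the final state with CELLS reset to ``cells0`` (signaling does not depend
    on cell number, so the baseline can be re-anchored freely)."""
    traj = simulate_system(params, NoDrug(), (0.0, days),
                           t_eval=np.array([0.0, days]))
    st = traj.final_state()
    st.cells = cells0
    st.time = 0.0
    return st


def _is_stationary(params: SignalingParams, state: NetworkState,
                   tol: float = 1e-4) -> bool:
    pd_ = params.to_dict()
    nodes = cascade_arrays(pd_, *state.fb)
    d = state_derivatives(pd_, *state.fb, state.td1, state.cells, nodes)
    return max(abs(float(x)) for x in d[:5]) < tol


def simulate_perk_timecourse(params: SignalingParams,
                             brafi_suppression: float = 0.95,
                             duration_h: float = 48.0,
                             initial_state: NetworkState | None = None,
                             n_points: int = 97) -> tuple:
    """pERK (ERK node activity) under generic BRAF inhibition, normalized to
    the drug-free steady-state baseline.

    Returns ``(t_hours, perk_relative)``.  The model is pre-equilibrated
    drug-free; an explicitly supplied non-stationary initial state raises,
    because rebound is defined relative to a steady baseline.
    """
    if not 0.0 <= brafi_suppression < 1.0:
        raise ValueError("suppression must lie in [0, 1)")
    if initial_state is None:
        initial_state = equilibrate(params)
    elif not _is_stationary(params, initial_state):
        raise ValueError("initial state is not a drug-free steady state; "
                         "pre-equilibrate before simulating rebound")
    baseline = float(cascade_arrays(params.to_dict(), *initial_state.fb)["ERK"])
    if baseline <= 0:
        raise ValueError("baseline ERK activity is zero; cannot normalize")
    exposure = TargetSuppression({"BRAF": brafi_suppression})
    t_eval = np.linspace(0.0, duration_h / 24.0, n_points)
    traj = simulate_system(params, exposure, (0.0, duration_h / 24.0),
                           initial_state=initial_state, t_eval=t_eval)
    return traj.t * 24.0, traj.nodes["ERK"] / baseline


def simulate_invitro_growth(params: SignalingParams,
                            exposure=None,
                            duration_h: float = 72.0) -> float:
    """Fold expansion CELLS(duration)/CELLS(0) of a drug-free-equilibrated
    culture under the given exposure (suppression or concentrations)."""
    state = equilibrate(params, cells0=1.0)
    traj = simulate_system(params, exposure, (0.0, duration_h / 24.0),
                           initial_state=state,
                           t_eval=np.array([0.0, duration_h / 24.0]))
    return float(traj.cells[-1] / traj.cells[0])
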