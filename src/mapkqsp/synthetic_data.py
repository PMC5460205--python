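"""Seeded generators for every input the calibration pipeline consumes.

Each generator simulates the model from a known ground truth, adds a
documented noise model, and returns ``(data, truth)`` so parameter-recovery
and end-to-end weighting experiments are testable without any external
download.  Default noise levels: 2% multiplicative for viability, 10%
multiplicative for tumor volumes, 5% of baseline additive for pERK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine, fitted
from .calibration_targets import CRC, MELANOMA
from .core_model import SignalingParams, apply_genotype, hill
from .pk import DRUG_LIBRARY, build_regimen, ensemble_concentration
from .virtual_population import (CohortSpec, DEFAULT_CLINICAL_BINS,
                                 ClinicalBins, generate_cohort)

__all__ = [
    "SyntheticSpec", "gen_perk_timecourses", "gen_viability_curves",
    "gen_xenograft_curves", "gen_clinical_bins", "XENOGRAFT_MODELS",
    "xenograft_baseline_params", "XENOGRAFT_ARMS", "murine_arm_exposures",
]


@dataclass
class SyntheticSpec:
    """Generator configuration; the seed is mandatory."""

    seed: int
    truth_overrides: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float | None = None
    design: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


# ---------------------------------------------------------------------------
# pERK time courses (0–48 h under 95% BRAF suppression)


def gen_perk_timecourses(spec: SyntheticSpec,
                         base: SignalingParams | None = None):
    """CRC-like and melanoma-like normalized pERK(t) tables.

    Simulates the fitted baseline under 95% generic BRAF suppression for
    both tissue contexts and adds additive Gaussian noise (default 5% of
    the baseline signal).  Returns ``(tidy DataFrame, truth dict)``.
    """
    base = base or fitted.default_params()
    noise = 0.05 if spec.noise_sd is None else spec.noise_sd
    t_h = np.asarray(spec.design.get("t_h", np.arange(0.0, 49.0, 2.0)), float)
    suppression = spec.design.get("suppression", 0.95)
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth = {"suppression": suppression, "noise_sd": noise, "conditions": {}}
    for name, genotype in (("CRC", CRC), ("melanoma", MELANOMA)):
        p = {k: np.asarray(v, float)
             for k, v in apply_genotype(base, genotype).to_dict().items()}
        for k, v in spec.truth_overrides.items():
            p[k] = np.asarray(v, float)
        fb0, td10, nodes0 = _engine.equilibrate(p)
        res = _engine.simulate(p, t_h.max() / 24.0, 0.01, fb0=fb0, td10=td10,
                               suppression={"BRAF": suppression},
                               record_nodes=("ERK",))
        erk_t = res["ERK"].reshape(res["t"].size, -1)[:, 0]
        clean = np.interp(t_h / 24.0, res["t"], erk_t)
        clean = clean / max(float(nodes0["ERK"]), 1e-12)
        noisy = clean + rng.standard_normal(t_h.size) * noise
        truth["conditions"][name] = {"t_h": t_h.tolist(),
                                     "perk": clean.tolist()}
        for t, v in zip(t_h, noisy):
            rows.append({"condition": name, "time_h": t, "perk": v})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# viability dose–response curves (96 h)


def gen_viability_curves(spec: SyntheticSpec,
                         base: SignalingParams | None = None,
                         drugs: Sequence[str] = ("vemurafenib", "cobimetinib",
                                                 "gdc0994"),
                         n_sensitive: int = 7, n_resistant: int = 7):
    """Cell line × drug × dose viability tables with known IC50 truth.

    Sensitive lines are fully MAPK-dependent (wOR = 1); resistant lines
    have wOR = 0.85.  Doses span a 9-point half-log grid bracketing each
    drug's target IC50; noise is multiplicative log-normal (default 2%).
    Viability is normalized to the untreated culture at 96 h.
    """
    base = base or fitted.default_params()
    noise = 0.02 if spec.noise_sd is None else spec.noise_sd
    rng = np.random.default_rng(spec.seed)
    duration_h = spec.design.get("duration_h", 96.0)
    rows = []
    truth = {"wOR_sensitive": 1.0, "wOR_resistant": 0.85, "noise_sd": noise,
             "ic50": {}, "hill": {}}
    lines = [(f"S{i + 1}", 1.0) for i in range(n_sensitive)] + \
            [(f"R{i + 1}", 0.85) for i in range(n_resistant)]
    for drug in drugs:
        d = DRUG_LIBRARY[drug]
        ic50 = spec.truth_overrides.get(f"ic50_{drug}", d.ic50)
        hill_i = spec.truth_overrides.get(f"hill_{drug}", d.hill_i)
        truth["ic50"][drug] = ic50
        truth["hill"][drug] = hill_i
        doses = ic50 * 10.0 ** np.linspace(-2.0, 2.0, 9)
        tau_field = {"RTK1": "taui1", "BRAF": "taui2", "MEK": "taui3",
                     "ERK": "taui4"}[d.target]
        for line, wor in lines:
            p = apply_genotype(base, CRC).replace(
                wOR=wor, **{tau_field: ic50, "ki" + tau_field[-1]: hill_i}
            ).to_dict()
            p = {k: np.asarray(v, float) for k, v in p.items()}
            fb0, td10, _ = _engine.equilibrate(p)
            grid = np.concatenate([[0.0], doses])
            res = _engine.simulate(p, duration_h / 24.0, 0.02,
                                   fb0=fb0, td10=td10,
                                   const_conc={d.target: grid})
            folds = res["cells"][-1]
            viab = folds[1:] / folds[0]
            noisy = viab * np.exp(rng.standard_normal(doses.size) * noise)
            for dose, v in zip(doses, noisy):
                rows.append({"cell_line": line, "drug": drug,
                             "dose": dose, "viability": v})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# xenograft tumor-volume time series


#: treatment arms of the 21-day xenograft experiment (13 + control).
XENOGRAFT_ARMS: tuple = (
    "control",
    "cetuximab", "vemurafenib", "cobimetinib", "gdc0994",
    "cetuximab+vemurafenib", "cetuximab+cobimetinib", "cetuximab+gdc0994",
    "vemurafenib+cobimetinib", "vemurafenib+gdc0994", "cobimetinib+gdc0994",
    "cetuximab+vemurafenib+cobimetinib", "vemurafenib+cobimetinib+gdc0994",
    "cetuximab+vemurafenib+cobimetinib+gdc0994",
)

#: tumor-model narratives: proliferation rate, alternate-receptor activity
#: and MAPK dependence distinguish the three in vivo models.
XENOGRAFT_MODELS: dict = {
    "HT29": {"muMAX": 0.23, "RTK2t": 0.039, "wOR": 1.0},
    "CR1472": {"muMAX": 0.28, "RTK2t": 0.39, "wOR": 0.78},
    "CRC15": {"muMAX": 0.17, "RTK2t": 0.039, "wOR": 1.0},
}

#: untreated 21-day fold-change anchors used to place the shared in vivo
#: death rate: the fast HT29 line grows ~4-fold and the slow CRC15 PDX
#: ~2.7-fold over three weeks.
_FOLD_ANCHORS = (("HT29", 4.0), ("CRC15", 2.7))


def _invivo_growth_overrides(base: SignalingParams,
                             vmax_fold: float = 10.0) -> dict:
    """In vivo death rate and growth half-max anchored to the untreated
    fold changes.

    Inverting the logistic closed form (carrying capacity ``vmax_fold`` ×
    baseline) gives the net growth rate each anchor requires; the pair of
    anchors then determines the drug-free growth-activation level
    H = Hill(S6_ss) and the shared death rate, and the growth half-max
    ``taug`` is re-anchored so the fitted baseline's S6 steady state
    produces exactly that activation."""
    K = vmax_fold
    rates = {}
    for name, f in _FOLD_ANCHORS:
        rates[name] = np.log((K - 1.0) * f / (K - f)) / 21.0
    mu1 = XENOGRAFT_MODELS[_FOLD_ANCHORS[0][0]]["muMAX"]
    mu2 = XENOGRAFT_MODELS[_FOLD_ANCHORS[1][0]]["muMAX"]
    r1, r2 = rates[_FOLD_ANCHORS[0][0]], rates[_FOLD_ANCHORS[1][0]]
    h = (r1 - r2) / (mu1 - mu2)
    if not 0.0 < h < 1.0:
        raise RuntimeError("fold anchors require an unattainable activation")
    delta = mu1 * h - r1
    p = {k: np.asarray(v, float)
         for k, v in apply_genotype(base, CRC).to_dict().items()}
    _, td1, _ = _engine.equilibrate(p)
    s6 = float(np.asarray(td1).reshape(-1)[0])
    taug = s6 * ((1.0 - h) / h) ** (1.0 / base.kg)
    return {"deltaMAX": float(max(delta, 1e-4)), "taug": float(taug)}


def xenograft_baseline_params(model: str = "HT29",
                              base: SignalingParams | None = None,
                              v0: float = 200.0,
                              vmax_fold: float = 10.0) -> SignalingParams:
    """In vivo truth parameters for a named xenograft model."""
    base = base or fitted.default_params()
    if model not in XENOGRAFT_MODELS:
        raise ValueError(f"unknown xenograft model {model!r}")
    over = dict(XENOGRAFT_MODELS[model])
    over.update(_invivo_growth_overrides(base, vmax_fold=vmax_fold))
    over["VMAX"] = vmax_fold * v0
    return apply_genotype(base, CRC).replace(**over)


def murine_arm_exposures(duration: float = 21.0, dt: float = 0.02,
                         arms: Sequence[str] = XENOGRAFT_ARMS) -> dict:
    """Per-arm tumor concentration half-grids for murine MTD regimens."""
    grids = {}
    for name in ("cetuximab", "vemurafenib", "cobimetinib", "gdc0994"):
        d = DRUG_LIBRARY[name].for_species("mouse")
        reg = build_regimen(name + "_murine", duration_d=duration)
        grids[name] = ensemble_concentration(d, reg, duration, dt,
                                             body_kg=0.025)
    out = {}
    for arm in arms:
        drugs = [] if arm == "control" else arm.split("+")
        out[arm] = {DRUG_LIBRARY[d].target: grids[d] for d in drugs}
    return out


def gen_xenograft_curves(spec: SyntheticSpec, model: str = "HT29",
                         base: SignalingParams | None = None,
                         arms: Sequence[str] = XENOGRAFT_ARMS,
                         n_replicates: int = 8, n_control: int = 10,
                         v0: float = 200.0):
    """21-day tumor-volume series (measured every 3 days) for 14 arms.

    Replicate-level noise is multiplicative log-normal (default 10%).
    Returns ``(DataFrame(arm, replicate, day, volume), truth params)``.
    """
    noise = 0.10 if spec.noise_sd is None else spec.noise_sd
    days = np.asarray(spec.design.get("days", np.arange(0.0, 22.0, 3.0)), float)
    dt = 0.02
    truth = xenograft_baseline_params(model, base=base, v0=v0)
    if spec.truth_overrides:
        truth = truth.replace(**dict(spec.truth_overrides))
    exposures = murine_arm_exposures(duration=float(days.max()), dt=dt,
                                     arms=arms)
    p = {k: np.asarray(v, float) for k, v in truth.to_dict().items()}
    fb0, td10, _ = _engine.equilibrate(p)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for arm in arms:
        res = _engine.simulate(p, float(days.max()), dt, fb0=fb0, td10=td10,
                               cells0=v0, conc_half_grid=exposures[arm] or None)
        clean = np.interp(days, res["t"], res["cells"])
        n_rep = n_control if arm == "control" else n_replicates
        for rep in range(n_rep):
            noisy = clean * np.exp(rng.standard_normal(days.size) * noise)
            for day, v in zip(days, noisy):
                rows.append({"arm": arm, "replicate": rep, "day": day,
                             "volume": v})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# binned clinical waterfalls


def gen_clinical_bins(spec: SyntheticSpec, n_truth: int = 500,
                      base: SignalingParams | None = None,
                      horizon_d: float = 56.0, dt: float = 0.02):
    """Synthetic Phase-1-style binned waterfalls from a ground-truth
    population.

    Draws a truth population from the published parameter distributions,
    simulates the three clinically tested combination arms with population
    PK, and bins the best 8-week changes.  Returns ``(ClinicalBins, truth
    dict)`` where the truth records the population's own per-arm ORRs
    (including ERKi monotherapy) for recovery experiments.
    """
    from .trial_simulation import TrialSimulator, CLINICAL_WEIGHTING_ARMS, \
        compute_orr
    base = base or fitted.clinical_baseline_params()
    cohort = generate_cohort(CohortSpec(n=n_truth, seed=spec.seed), base=base)
    sim = TrialSimulator(cohort, seed=spec.seed, horizon_d=horizon_d, dt=dt)
    freqs = {}
    counts = {}
    truth = {"seed": spec.seed, "n": n_truth, "orr": {}}
    bins = DEFAULT_CLINICAL_BINS
    for arm in CLINICAL_WEIGHTING_ARMS:
        df = sim.percent_changes(arm)
        idx = bins.assign(df["pct_best_8wk"].to_numpy())
        c = np.bincount(idx, minlength=len(bins.labels))
        counts[arm] = c
        freqs[arm] = 100.0 * c / c.sum()
        truth["orr"][arm] = compute_orr(df["pct_best_8wk"].to_numpy())
    for arm in ("gdc0994", "cobimetinib"):
        df = sim.percent_changes(arm)
        truth["orr"][arm] = compute_orr(df["pct_best_8wk"].to_numpy())
    out = ClinicalBins(frequencies=freqs, counts=counts)
    return out, truth
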