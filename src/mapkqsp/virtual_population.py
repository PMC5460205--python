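"""Virtual tumor cohorts and prevalence weighting against clinical data.

A virtual cohort is a Monte Carlo sample of tumors: 16 cellular parameters
(receptor/kinase expression and basal activity, feedback gains, death rate,
pathway-dependence weights) drawn from log-normal distributions around
published central values, on top of a BRAF-V600E baseline parameter set.

Prevalence weighting assigns each virtual tumor a probability (prevalence
weight, PW) such that the weighted distribution of simulated 8-week tumor
size changes reproduces the binned waterfall distributions observed in
three published Phase 1 trials (EGFRi+BRAFi, BRAFi+MEKi, and
EGFRi+BRAFi+MEKi combinations in BRAF-V600E colorectal cancer).  The
weights solve the quadratic program

    min ½·xᵀx   s.t.  A_eq·x = b_eq,  x ≥ 0,

with H = identity, bin-membership indicator rows stacked across the three
arms plus a sum-to-one row.  With a finite cohort exact equality can be
numerically infeasible, so the default solver minimizes
``||x||² + rho·||A_eq·x − b_eq||²`` over x ≥ 0 (a soft-constraint variant
that reduces to the exact program as rho → ∞), implemented via
non-negative least squares.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_model import SignalingParams, Genotype, apply_genotype

__all__ = [
    "POPULATION_DISTRIBUTIONS", "CohortSpec", "Cohort", "ClinicalBins",
    "DEFAULT_CLINICAL_BINS", "CLINICAL_ARMS", "generate_cohort",
    "prevalence_weight", "resample_population",
]

#: published per-parameter (median, variance of log10) for the virtual
#: population; medians are the central-value column of the source table.
POPULATION_DISTRIBUTIONS: tuple = (
    ("BRAFt", 1.0, 1.0),
    ("CRAFt", 1.0, 1.0),
    ("deltaMAX", 0.04, 0.1),
    ("G13", 0.5, 1.0),
    ("Gdusp", 0.5, 1.0),
    ("Gspry", 0.5, 1.0),
    ("MEKb", 0.01, 2.0),
    ("MEKt", 1.0, 1.0),
    ("PI3Kb", 0.05, 2.0),
    ("PI3Kt", 1.0, 1.0),
    ("RASb", 0.05, 1.0),
    ("RASt", 1.5, 1.0),
    ("RTK1t", 0.25, 2.0),
    ("RTK2t", 0.1, 2.0),
    ("wOR", 1.0, 0.1),
    ("wRAS", 0.9, 0.1),
)

#: response bins, ascending in % change from baseline.  The published table
#: prints an overlapping bottom bin ("−100:−30"); it is read as −100:−50 so
#: the seven bins partition [−100, ∞).
BIN_EDGES = (-100.0, -50.0, -30.0, 0.0, 20.0, 50.0, 100.0, np.inf)
BIN_LABELS = ("-100:-50", "-50:-30", "-30:0", "0:20", "20:50", "50:100",
              "100+")

CLINICAL_ARMS = ("cetuximab+vemurafenib", "vemurafenib+cobimetinib",
                 "cetuximab+vemurafenib+cobimetinib")


@dataclass(frozen=True)
class ClinicalBins:
    """Binned tumor-size-change distributions per trial arm.

    ``frequencies`` holds the published percent values (per arm, ascending
    bins, summing to ~100); ``counts`` the patient counts.
    """

    edges: tuple = BIN_EDGES
    labels: tuple = BIN_LABELS
    frequencies: Mapping[str, np.ndarray] = field(default_factory=dict)
    counts: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for arm, f in self.frequencies.items():
            f = np.asarray(f, float)
            if f.size != len(self.labels):
                raise ValueError(f"{arm}: expected {len(self.labels)} bins")
            if abs(f.sum() - 100.0) > 0.5:
                raise ValueError(f"{arm}: frequencies sum to {f.sum()}, "
                                 "expected ~100 within rounding")

    def n_patients(self, arm: str) -> int:
        return int(np.sum(self.counts[arm]))

    def assign(self, pct_change) -> np.ndarray:
        """Bin index for each % change value."""
        x = np.asarray(pct_change, float)
        if np.any(x < -100.0 - 1e-9):
            raise ValueError("% change cannot be below -100")
        return np.clip(np.searchsorted(self.edges[1:-1], x, side="right"),
                       0, len(self.labels) - 1)

    def to_frame(self) -> pd.DataFrame:
        rows = {"bin": list(self.labels)}
        for arm in self.frequencies:
            rows[arm + "_pct"] = np.asarray(self.frequencies[arm], float)
            rows[arm + "_n"] = np.asarray(self.counts[arm], int)
        return pd.DataFrame(rows)


#: published Phase 1 waterfall distributions (percent (count), ascending
#: bins) for the three clinically tested combinations.
DEFAULT_CLINICAL_BINS = ClinicalBins(
    frequencies={
        "cetuximab+vemurafenib":
            np.array([15.4, 7.7, 30.8, 30.8, 11.5, 3.8, 0.0]),
        "vemurafenib+cobimetinib":
            np.array([2.6, 10.5, 47.4, 26.3, 10.5, 2.6, 0.0]),
        "cetuximab+vemurafenib+cobimetinib":
            np.array([17.1, 20.0, 48.6, 11.4, 0.0, 2.9, 0.0]),
    },
    counts={
        "cetuximab+vemurafenib": np.array([4, 2, 8, 8, 3, 1, 0]),
        "vemurafenib+cobimetinib": np.array([1, 4, 18, 10, 4, 1, 0]),
        "cetuximab+vemurafenib+cobimetinib": np.array([6, 8, 16, 4, 0, 1, 0]),
    },
)


@dataclass
class CohortSpec:
    """Sampling spec: per-parameter (name, median, log10 variance)."""

    distributions: Sequence[tuple] = POPULATION_DISTRIBUTIONS
    n: int = 1000
    seed: int = 0
    genotype: Genotype = field(
        default_factory=lambda: Genotype(mutations=("BRAF_V600E",)))

    def __post_init__(self):
        known = set(SignalingParams.names())
        for name, mean, var in self.distributions:
            if name not in known:
                raise ValueError(f"unknown parameter {name!r} in spec")
            if mean <= 0 or var < 0:
                raise ValueError(f"invalid (median, variance) for {name!r}")
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")


@dataclass
class Cohort:
    """Sampled virtual tumors: full parameter table + prevalence weights."""

    params: pd.DataFrame         # n rows × all SignalingParams columns
    weights: np.ndarray
    sampled_names: tuple
    base: SignalingParams
    pk_etas: dict = field(default_factory=dict)   # drug -> param DataFrame

    def __len__(self):
        return len(self.params)

    def param_hash(self) -> str:
        return hashlib.sha256(
            self.params.to_csv(index=False).encode()).hexdigest()

    def tumor(self, i: int) -> SignalingParams:
        return SignalingParams.from_dict(self.params.iloc[i].to_dict())

    def to_csv(self, path) -> None:
        df = self.params.copy()
        df.insert(0, "tumor_id", np.arange(len(df)))
        df["PW"] = self.weights
        df.to_csv(path, index=False)


def _sample_batch(spec: CohortSpec, bd: dict, rng, n: int) -> dict:
    table = {name: np.full(n, v, dtype=float) for name, v in bd.items()}
    names = []
    for name, median, var in spec.distributions:
        eta = rng.standard_normal(n) * np.sqrt(var)
        table[name] = median * 10.0 ** eta
        names.append(name)
    # pathway weights and feedback gains are fractions (a gain above 1
    # would drive node activities negative); clip the unbounded draws
    for w in ("wOR", "wRAS", "G13", "Gdusp", "Gspry", "G23", "G33", "G34"):
        if w in names:
            table[w] = np.clip(table[w], 0.0, 1.0)
    # basal activity may not exceed maximal activity; raise the maximum
    # rather than erase the sampled activation (a V600E tumor keeps its
    # 0.9 basal BRAF drive even when BRAFt samples below it)
    for node in ("RTK1", "RTK2", "RTK3", "RAS", "BRAF", "CRAF", "MEK",
                 "ERK", "PI3K", "AKT", "S6"):
        table[node + "t"] = np.maximum(table[node + "b"], table[node + "t"])
    return table, names


def _grows_untreated(table: dict) -> np.ndarray:
    """Admissibility: drug-free net growth rate is positive."""
    from . import _engine
    from .core_model import hill
    p = {k: np.asarray(v, float) for k, v in table.items()}
    _, td1, _ = _engine.equilibrate(p)
    rate = p["muMAX"] * hill(td1, p["taug"], p["kg"]) - p["deltaMAX"]
    return np.asarray(rate) > 0.0


def generate_cohort(spec: CohortSpec,
                    base: SignalingParams | None = None,
                    require_growth: bool = True) -> Cohort:
    """Monte Carlo cohort: parameter_i = median_i · 10^η, η ~ N(0, var).

    Draws are deterministic given the seed; weights start uniform (1/n).
    Pathway weights and feedback gains are clipped to [0, 1] and maximal
    activities raised to their sampled basals so every tumor is an
    admissible parameter set.  With ``require_growth`` (default) candidate
    tumors whose untreated net growth rate is not positive are rejected
    and redrawn — a tumor that shrinks spontaneously could not have
    presented clinically.  The default base is the fitted clinical
    baseline.
    """
    if base is None:
        from .fitted import clinical_baseline_params
        base = clinical_baseline_params()
    base = apply_genotype(base, spec.genotype)
    rng = np.random.default_rng(spec.seed)
    bd = base.to_dict()
    kept: list = []
    names: tuple = ()
    n_kept = 0
    attempts = 0
    while n_kept < spec.n:
        batch = max(spec.n - n_kept, 64)
        table, names = _sample_batch(spec, bd, rng, batch)
        if require_growth:
            ok = _grows_untreated(table)
        else:
            ok = np.ones(batch, bool)
        kept.append({k: v[ok] for k, v in table.items()})
        n_kept += int(ok.sum())
        attempts += 1
        if attempts > 200:
            raise RuntimeError("viability screen rejected almost all draws; "
                               "check the baseline growth parameters")
    table = {k: np.concatenate([b[k] for b in kept])[:spec.n] for k in bd}
    params = pd.DataFrame(table)[list(SignalingParams.names())]
    weights = np.full(spec.n, 1.0 / spec.n)
    return Cohort(params=params, weights=weights, sampled_names=tuple(names),
                  base=base)


# ---------------------------------------------------------------------------
# prevalence weighting (quadratic program)


def _membership_matrix(simulated: Mapping[str, np.ndarray],
                       bins: ClinicalBins, arms: Sequence[str]):
    rows = []
    targets = []
    row_names = []
    n = None
    for arm in arms:
        changes = np.asarray(simulated[arm], float)
        if n is None:
            n = changes.size
        elif changes.size != n:
            raise ValueError("simulated arms differ in cohort size")
        idx = bins.assign(changes)
        freq = np.asarray(bins.frequencies[arm], float)
        freq = freq / freq.sum()
        for b, label in enumerate(bins.labels):
            member = (idx == b).astype(float)
            if freq[b] > 0 and member.sum() == 0:
                raise ValueError(
                    f"infeasible: no virtual tumor falls in bin {label!r} of "
                    f"arm {arm!r} (clinical frequency {freq[b]:.3f})")
            rows.append(member)
            targets.append(freq[b])
            row_names.append(f"{arm}|{label}")
    rows.append(np.ones(n))
    targets.append(1.0)
    row_names.append("sum")
    return np.asarray(rows), np.asarray(targets), row_names


def prevalence_weight(simulated: Mapping[str, np.ndarray],
                      bins: ClinicalBins = DEFAULT_CLINICAL_BINS,
                      arms: Sequence[str] = CLINICAL_ARMS,
                      rho: float = 1e8):
    """Minimum-norm nonnegative prevalence weights matching clinical bins.

    ``simulated`` maps each weighting arm to the per-tumor simulated %
    tumor-size changes.  Returns ``(weights, diagnostics)`` where
    diagnostics is a DataFrame of achieved vs target bin frequencies and
    residuals.  Raises when a clinically populated bin contains no virtual
    tumor (naming the empty arm/bin cells).
    """
    A, b, row_names = _membership_matrix(simulated, bins, arms)
    n = A.shape[1]
    sr = np.sqrt(rho)
    # min ||x||^2 + rho ||Ax-b||^2 over x>=0  ==  NNLS on [[sqrt(rho) A];[I]]
    M = np.vstack([sr * A, np.eye(n)])
    y = np.concatenate([sr * b, np.zeros(n)])
    x, _ = nnls(M, y)
    total = x.sum()
    if total <= 0:
        raise RuntimeError("prevalence weighting returned all-zero weights")
    x = x / total
    achieved = A @ x
    diag = pd.DataFrame({"constraint": row_names, "target": b,
                         "achieved": achieved, "residual": achieved - b})
    return x, diag


def resample_population(cohort: Cohort, n_out: int, seed) -> np.ndarray:
    """Multinomial resample of tumor indices with probability ∝ PW."""
    w = np.asarray(cohort.weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("all-zero weight vector cannot be resampled")
    rng = np.random.default_rng(seed)
    return rng.choice(len(w), size=n_out, replace=True, p=w / w.sum())
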