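"""Two-step MEK→ERK mass-action sub-model and its closed-form steady state.

ERK is activated by doubly phosphorylated MEK (ppMEK) in two distributive
phosphorylation steps (ERK → pERK → ppERK) and deactivated by a phosphatase
(pAse); at steady state the doubly phosphorylated fraction of ERK is

    ppERK/ERK_T = f1·f2·q² / (r1·r2·pAse² + f1·r2·pAse·q + f1·f2·q²),

with q = ppMEK.  The curve rises steeply at low ppMEK — a biochemical
amplifier — which is why near-complete MEK inhibition is required to shut
down ERK output, and why targeting ERK directly is less susceptible to
pathway reactivation.

Default parameters are the published HeLa-cell rate constants; abundances
can be used raw (molecules/cell) or normalized to total MEK, in which units
pAse = 0.45 and ERK_T* = 0.95.  The sub-model's ``r1``/``r2`` are reverse
rate constants, unrelated to the core model's feedback rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["MassActionParams", "pperk_fraction", "submodel_trajectory",
           "halfmax_ppmek", "export_curve"]

#: published rate constants (per second per unit abundance).
F1 = 5.3e7
F2 = 1.9e7
R1 = 5.6e6
R2 = 3.6e6


@dataclass(frozen=True)
class MassActionParams:
    """Rate constants and abundances of the MEK→ERK sub-model."""

    f1: float = F1
    f2: float = F2
    r1: float = R1
    r2: float = R2
    pase: float = 0.45          # phosphatase abundance (MEK_T-normalized)
    mek_t: float = 1.0          # total MEK (1.0 in normalized units)
    erk_t: float = 0.95         # total ERK (ERK_T* in normalized units)

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    @classmethod
    def molecules_per_cell(cls) -> "MassActionParams":
        """Raw published abundances (molecules/cell) for traceability."""
        return cls(pase=1.0e7, mek_t=2.2e7, erk_t=2.1e7)


def pperk_fraction(ppmek, p: MassActionParams = MassActionParams()):
    """Steady-state fraction of total ERK doubly phosphorylated.

    Strictly increasing in ppMEK, 0 at 0 and → 1 as ppMEK → ∞; total ERK
    cancels in the fraction.
    """
    q = np.asarray(ppmek, dtype=float)
    if np.any(q < 0):
        raise ValueError("ppMEK must be nonnegative")
    num = p.f1 * p.f2 * q ** 2
    den = p.r1 * p.r2 * p.pase ** 2 + p.f1 * p.r2 * p.pase * q + num
    return num / den


def halfmax_ppmek(p: MassActionParams = MassActionParams()) -> float:
    """ppMEK at which the steady-state ppERK fraction reaches 1/2
    (positive root of f1·f2·q² = r1·r2·pAse² + f1·r2·pAse·q)."""
    a = p.f1 * p.f2
    b = -p.f1 * p.r2 * p.pase
    c = -p.r1 * p.r2 * p.pase ** 2
    return float((-b + np.sqrt(b * b - 4 * a * c)) / (2 * a))


def submodel_trajectory(p: MassActionParams, ppmek: float,
                        t_span: tuple = (0.0, 60.0),
                        initial: tuple | None = None,
                        n_points: int = 201):
    """Integrate the three-state (ERK, pERK, ppERK) system at fixed ppMEK.

    ``initial`` must be nonnegative and sum to ERK_T (default: all
    unphosphorylated).  Time is rescaled internally so the published rate
    constants (1/s scale) integrate comfortably; ``t_span`` is in units of
    the slowest relaxation time.  Mass ERK+pERK+ppERK is conserved exactly
    by construction of the equations.

    Returns ``(t, states)`` with states shape (n, 3).
    """
    if ppmek < 0:
        raise ValueError("ppMEK must be nonnegative")
    if initial is None:
        initial = (p.erk_t, 0.0, 0.0)
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0) or abs(initial.sum() - p.erk_t) > 1e-9 * p.erk_t:
        raise ValueError("initial states must be nonnegative and sum to ERK_T")
    # rescale time by the characteristic deactivation rate
    scale = p.r1 * p.pase

    def rhs(t, y):
        erk, perk, pperk = y
        act1 = p.f1 * ppmek * erk
        deact1 = p.r1 * p.pase * perk
        act2 = p.f2 * ppmek * perk
        deact2 = p.r2 * p.pase * pperk
        return ((deact1 - act1) / scale,
                (act1 - deact1 - act2 + deact2) / scale,
                (act2 - deact2) / scale)

    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(rhs, t_span, initial, method="LSODA", t_eval=t_eval,
                    rtol=1e-10, atol=1e-12 * p.erk_t)
    if not sol.success:
        raise RuntimeError(f"sub-model integration failed: {sol.message}")
    return sol.t, sol.y.T


def export_curve(path, ppmek_grid=None,
                 p: MassActionParams = MassActionParams()) -> None:
    """Write the (ppMEK, ppERK fraction) curve as CSV."""
    import pandas as pd
    if ppmek_grid is None:
        ppmek_grid = np.logspace(-3, 1, 81) * p.mek_t
    pd.DataFrame({"ppMEK": ppmek_grid,
                  "ppERK_fraction": pperk_fraction(ppmek_grid, p)}
                 ).to_csv(path, index=False)
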