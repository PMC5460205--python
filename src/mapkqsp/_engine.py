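"""Vectorized fixed-step integration of the signaling/growth system.

The public single-trajectory path (:func:`mapkqsp.core_model.simulate_system`)
uses an adaptive stiff-capable solver.  Cohort-scale work — 1000-tumor
virtual populations, PSO swarms, sensitivity scans — instead uses this
engine: a classical RK4 with a fixed step, vectorized across ensemble
members via NumPy broadcasting.  Once pharmacokinetics are propagated by
exact matrix exponentials (see :mod:`mapkqsp.pk`), the remaining six states
(FB1..FB4, TD1, CELLS) are non-stiff on the day time scale, so a step of
0.01–0.02 days resolves them to well below the Monte Carlo noise of any
population-level quantity; agreement with the adaptive reference path is
asserted in the test suite.

Parameters are passed as a mapping name -> scalar or ``(n,)`` array;
exposures as constant suppression fractions and/or per-drug concentration
arrays sampled on the *half-step* grid (2*n_steps + 1 points), which is
exactly what RK4 stage evaluations require.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .core_model import cascade_arrays, state_derivatives

__all__ = ["steady_state", "equilibrate", "simulate", "params_to_arrays"]


def params_to_arrays(table) -> dict:
    """Column dict (name -> (n,) float array) from a pandas DataFrame or a
    mapping of scalars/arrays."""
    try:
        cols = {c: np.asarray(table[c], dtype=float) for c in table.columns}
    except AttributeError:
        cols = {k: np.asarray(v, dtype=float) for k, v in table.items()}
    return cols


def steady_state(p: Mapping[str, float | np.ndarray],
                 suppression: Mapping[str, float | np.ndarray] | None = None,
                 conc: Mapping[str, float | np.ndarray] | None = None,
                 damping: float = 0.3, iters: int = 400, tol: float = 1e-10,
                 ) -> tuple:
    """Damped fixed-point solve of the stationarity conditions.

    At steady state each feedback transit equals its driver (FB1..3 = ERK,
    FB4 = AKT, TD1 = S6), so the fixed point is found by damped iteration on
    the feedback states.  Returns ``(fb (..,4 tuple), td1, nodes)``.
    """
    shape = np.broadcast_shapes(*(np.shape(v) for v in p.values())) or ()
    fb1 = np.zeros(shape)
    fb2 = np.zeros(shape)
    fb3 = np.zeros(shape)
    fb4 = np.zeros(shape)
    for _ in range(iters):
        nodes = cascade_arrays(p, fb1, fb2, fb3, fb4, conc=conc,
                               suppression=suppression)
        n1 = fb1 + damping * (nodes["ERK"] - fb1)
        n2 = fb2 + damping * (nodes["ERK"] - fb2)
        n3 = fb3 + damping * (nodes["ERK"] - fb3)
        n4 = fb4 + damping * (nodes["AKT"] - fb4)
        delta = max(np.max(np.abs(n1 - fb1)), np.max(np.abs(n4 - fb4)))
        fb1, fb2, fb3, fb4 = n1, n2, n3, n4
        if delta < tol:
            break
    nodes = cascade_arrays(p, fb1, fb2, fb3, fb4, conc=conc,
                           suppression=suppression)
    return (fb1, fb2, fb3, fb4), nodes["S6"], nodes


def equilibrate(p: Mapping[str, float | np.ndarray],
                days: float = 20.0, dt: float = 0.05,
                suppression: Mapping[str, float | np.ndarray] | None = None,
                conc: Mapping[str, float | np.ndarray] | None = None,
                ) -> tuple:
    """Pre-equilibration by integration: a damped fixed-point initial guess
    refined by RK4 relaxation of the true dynamics.

    The fixed-point map alone can select the wrong branch when steep
    negative feedback makes it oscillatory; integrating the transit-
    compartment ODEs settles on the state the reference solver reaches.
    Returns ``(fb (4-tuple), td1, nodes)``.
    """
    fb0, td10, _ = steady_state(p, suppression=suppression, conc=conc,
                                damping=0.2, iters=150)
    res = simulate(p, days, dt, fb0=fb0, td10=td10, cells0=1.0,
                   suppression=suppression, const_conc=conc)
    fb = tuple(res["fb"])
    td1 = res["td1"][-1]
    nodes = cascade_arrays(p, *fb, conc=conc, suppression=suppression)
    return fb, td1, nodes


def simulate(p: Mapping[str, float | np.ndarray],
             duration: float,
             dt: float,
             fb0=None, td10=None, cells0=1.0,
             suppression: Mapping[str, float | np.ndarray] | None = None,
             conc_half_grid: Mapping[str, np.ndarray] | None = None,
             const_conc: Mapping[str, float | np.ndarray] | None = None,
             record_nodes: tuple = (),
             ) -> dict:
    """RK4-integrate the ensemble over ``duration`` days with step ``dt``.

    ``conc_half_grid`` maps target nodes to concentration arrays of shape
    ``(2*n_steps + 1,)`` or ``(2*n_steps + 1, n)`` sampled at half-step
    times.  ``const_conc`` is a time-constant alternative.  Returns a dict
    with the full-step time grid ``t``, trajectories ``cells`` and ``td1``
    of shape ``(n_steps + 1, ...)``, final feedback states ``fb``, and one
    trajectory per requested node name.
    """
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        dt = duration / n_steps
    shapes = [np.shape(v) for v in p.values()]
    if suppression:
        shapes += [np.shape(v) for v in suppression.values()]
    if const_conc:
        shapes += [np.shape(v) for v in const_conc.values()]
    if conc_half_grid:
        shapes += [np.shape(v)[1:] for v in conc_half_grid.values()]
    shape = np.broadcast_shapes(*shapes) or ()
    if fb0 is None:
        fb = [np.zeros(shape) for _ in range(4)]
    else:
        fb = [np.broadcast_to(np.asarray(f, float), shape).copy() for f in fb0]
    td1 = np.broadcast_to(np.asarray(
        0.0 if td10 is None else td10, float), shape).astype(float).copy()
    cells = np.broadcast_to(np.asarray(cells0, float), shape).astype(float).copy()

    if conc_half_grid is not None:
        n_half = 2 * n_steps + 1
        for node, arr in conc_half_grid.items():
            if arr.shape[0] != n_half:
                raise ValueError(
                    f"concentration grid for {node} has {arr.shape[0]} rows, "
                    f"expected {n_half}")

    def conc_at(h: int):
        if conc_half_grid is not None:
            return {node: arr[h] for node, arr in conc_half_grid.items()}
        return const_conc

    out_cells = np.empty((n_steps + 1,) + shape)
    out_td1 = np.empty((n_steps + 1,) + shape)
    out_nodes = {name: np.empty((n_steps + 1,) + shape) for name in record_nodes}
    sixth = dt / 6.0

    def deriv(y, h):
        nodes = cascade_arrays(p, y[0], y[1], y[2], y[3],
                               conc=conc_at(h), suppression=suppression)
        return state_derivatives(p, y[0], y[1], y[2], y[3], y[4], y[5], nodes), nodes

    y = fb + [td1, cells]
    out_cells[0] = y[5]
    out_td1[0] = y[4]
    if record_nodes:
        nodes0 = cascade_arrays(p, y[0], y[1], y[2], y[3],
                                conc=conc_at(0), suppression=suppression)
        for name in record_nodes:
            out_nodes[name][0] = nodes0[name]
    for i in range(n_steps):
        h = 2 * i
        k1, _ = deriv(y, h)
        y2 = [y[j] + 0.5 * dt * k1[j] for j in range(6)]
        k2, _ = deriv(y2, h + 1)
        y3 = [y[j] + 0.5 * dt * k2[j] for j in range(6)]
        k3, _ = deriv(y3, h + 1)
        y4 = [y[j] + dt * k3[j] for j in range(6)]
        k4, nodes_end = deriv(y4, h + 2)
        y = [y[j] + sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
             for j in range(6)]
        y[5] = np.maximum(y[5], 1e-12)           # CELLS stays positive
        out_cells[i + 1] = y[5]
        out_td1[i + 1] = y[4]
        if record_nodes:
            nodes = cascade_arrays(p, y[0], y[1], y[2], y[3],
                                   conc=conc_at(h + 2), suppression=suppression)
            for name in record_nodes:
                out_nodes[name][i + 1] = nodes[name]
    result = {"t": np.linspace(0.0, n_steps * dt, n_steps + 1),
              "cells": out_cells, "td1": out_td1,
              "fb": y[:4]}
    result.update(out_nodes)
    return result
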