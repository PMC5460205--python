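"""Shipped fitted signaling parameter sets.

Most cascade parameters are not individually identifiable, so the package
ships an ensemble of seeded PSO solutions (see ``scripts/fit_defaults.py``)
calibrated against the package's reference pERK-rebound and growth-phenotype
targets (:func:`mapkqsp.calibration_targets.reference_calibration_data`).
Analyses that depend on the fitted baseline use either the best set
(:func:`default_params`) or the whole ensemble (:func:`load_fitted_ensemble`).
"""

from __future__ import annotations

import json
from importlib import resources

from .core_model import SignalingParams

__all__ = ["load_fitted_ensemble", "default_params", "ensemble_mse",
           "clinical_baseline_params"]

_cache: dict = {}


def _load() -> dict:
    if "raw" not in _cache:
        path = resources.files("mapkqsp").joinpath("data/fitted_params.json")
        _cache["raw"] = json.loads(path.read_text())
    return _cache["raw"]


def load_fitted_ensemble() -> list:
    """All shipped fitted parameter sets, sorted by calibration MSE."""
    return [SignalingParams.from_dict(d) for d in _load()["sets"]]


def ensemble_mse() -> list:
    return list(_load()["mse"])


def default_params() -> SignalingParams:
    """The lowest-MSE fitted parameter set."""
    return SignalingParams.from_dict(_load()["sets"][0])


def clinical_baseline_params() -> SignalingParams:
    """Fitted baseline adapted to the clinical (virtual patient) context.

    Cellular signaling and IC50 parameters are conserved from the in vitro
    fit; growth-scale parameters are replaced by the in vivo/clinical
    overrides recorded next to the fit (slow net tumor growth on the
    months time scale, carrying capacity at 10× baseline tumor burden).
    """
    return default_params().replace(**_load().get("clinical_overrides", {}))
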