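"""Flat key-value parameter files (JSON or YAML) for model parameters.

Keys transliterate the model symbols: ``alpha``, ``beta``, ``W_break``,
``post_break_policy``, ``e``, ``k_F``, composition constants and
fractions, ``gamma_BS``/``gamma_BR``, ``a_NS``/``a_NR``,
``b_NS``/``b_NR``, ``delta`` and ``variant``.  Only constant-valued
fraction/maintenance fields are serializable; function hooks must be
constructed in code.  Round trips are lossless.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

import yaml

from .components import (
    CompositionParams,
    FeedingParams,
    IngestionParams,
    MaintenanceParams,
)
from .engine import ModelParams
from .exceptions import ConfigurationError

__all__ = ["params_to_dict", "params_from_dict", "save_params", "load_params"]

_COMPOSITION_KEYS = ("E_CP", "E_L", "E_MR", "E_SSD", "E_SSG", "E_SR",
                     "f_R", "f_G", "f_CP", "f_L", "p_R")
_MAINTENANCE_KEYS = ("gamma_BS", "gamma_BR", "a_NS", "a_NR", "b_NS", "b_NR", "delta")


def params_to_dict(p: ModelParams) -> dict:
    """Flatten a :class:`ModelParams` into a plain key-value dict."""
    if p.feeding.custom_fn is not None:
        raise ConfigurationError("custom feeding-cost functions are not serializable")
    out = {
        "alpha": p.ingestion.alpha,
        "beta": p.ingestion.beta,
        "W_break": "inf" if math.isinf(p.ingestion.W_break) else p.ingestion.W_break,
        "post_break_policy": p.ingestion.post_break_policy,
        "e": p.e,
        "k_F": p.feeding.k_F,
        "variant": p.variant,
    }
    for key in _COMPOSITION_KEYS:
        value = getattr(p.composition, key)
        if callable(value):
            raise ConfigurationError(f"composition hook {key} is not serializable")
        out[key] = value
    for key in _MAINTENANCE_KEYS:
        value = getattr(p.maintenance, key)
        if callable(value):
            raise ConfigurationError(f"maintenance hook {key} is not serializable")
        out[key] = value
    return out


def params_from_dict(d: dict) -> ModelParams:
    """Rebuild :class:`ModelParams` from a flat dict (missing keys -> defaults)."""
    d = dict(d)
    w_break = d.get("W_break", math.inf)
    if isinstance(w_break, str):
        w_break = math.inf if w_break in ("inf", ".inf", "Infinity") else float(w_break)
    ingestion = IngestionParams(
        alpha=float(d["alpha"]),
        beta=float(d.get("beta", 0.75)),
        W_break=w_break,
        post_break_policy=d.get("post_break_policy", "hold-allometry"),
    )
    comp_kwargs = {k: float(d[k]) for k in _COMPOSITION_KEYS if k in d}
    maint_kwargs = {k: float(d[k]) for k in _MAINTENANCE_KEYS if k in d}
    return ModelParams(
        ingestion=ingestion,
        composition=CompositionParams(**comp_kwargs),
        feeding=FeedingParams(k_F=float(d.get("k_F", 0.1))),
        maintenance=MaintenanceParams(**maint_kwargs),
        e=float(d.get("e", 0.8)),
        variant=d.get("variant", "simplified"),
    )


def save_params(p: ModelParams, path: Union[str, Path]) -> None:
    """Write parameters to ``path``; format chosen by extension (.json/.yaml)."""
    path = Path(path)
    data = params_to_dict(p)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_params(path: Union[str, Path]) -> ModelParams:
    """Read a parameter file written by :func:`save_params` (or by hand)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file {path} does not exist")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"parameter file {path} does not hold a mapping")
    try:
        return params_from_dict(data)
    except KeyError as exc:
        raise ConfigurationError(f"parameter file {path} is missing key {exc}") from exc
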