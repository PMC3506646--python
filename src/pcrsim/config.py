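"""Flat key-value configuration files for reaction and variation settings.

A config file is a YAML mapping whose keys match the field names of
:class:`~pcrsim.parameter_engine.ReactionConditions` and
:class:`~pcrsim.parameter_engine.VariationConfig`, e.g.::

    n0_mean: 50000
    emax: 1.9
    primer_conc: 260
    sigma_emax: 0.01
    side_reactions: false
    baseline: true

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .parameter_engine import ReactionConditions, VariationConfig

__all__ = ["load_config", "split_config"]

_COND_FIELDS = {f.name for f in fields(ReactionConditions)}
_VAR_FIELDS = {f.name for f in fields(VariationConfig)}


def split_config(mapping: dict) -> tuple[dict, dict]:
    """Split a flat mapping into reaction-condition and variation kwargs."""
    cond, var, unknown = {}, {}, []
    for key, value in mapping.items():
        if key in _COND_FIELDS:
            cond[key] = value
        elif key in _VAR_FIELDS:
            var[key] = value
        else:
            unknown.append(key)
    if unknown:
        valid = sorted(_COND_FIELDS | _VAR_FIELDS)
        raise ValueError(f"unknown config key(s) {unknown}; valid keys: {valid}")
    return cond, var


def load_config(path) -> tuple[ReactionConditions, VariationConfig]:
    """Read a flat YAML config into condition and variation objects."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    cond_kw, var_kw = split_config(mapping)
    if "n0_mean" not in cond_kw:
        raise ValueError(f"{path}: 'n0_mean' is required")
    return ReactionConditions(**cond_kw), VariationConfig(**var_kw)
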