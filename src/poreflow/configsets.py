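"""Named, shipped configuration sets (YAML under ``poreflow/configs``).

These pin the published analysis protocols — pore-region ring residues,
salt-bridge pair sets, the ATP-binding arginines, contact cutoff and the
permeability fitting protocol — so a run can reference them by name
instead of retyping residue lists.
"""

from __future__ import annotations

from functools import cache
from importlib import resources

import yaml

__all__ = [
    "pore_region_config",
    "saltbridge_pairs",
    "binding_defaults",
    "permeability_defaults",
    "available_pore_regions",
    "available_saltbridge_sets",
]


@cache
def _load(name: str) -> dict:
    ref = resources.files("poreflow") / "configs" / name
    return yaml.safe_load(ref.read_text())


def available_pore_regions() -> list[str]:
    return sorted(_load("pore_regions.yaml"))


def pore_region_config(name: str) -> dict:
    """Ring residue lists and radius for a named pore region (e.g. ``ucp2_h``)."""
    cfgs = _load("pore_regions.yaml")
    if name not in cfgs:
        raise KeyError(f"unknown pore region {name!r}; available: {sorted(cfgs)}")
    return dict(cfgs[name])


def available_saltbridge_sets() -> list[str]:
    return sorted(_load("saltbridge_pairs.yaml"))


def saltbridge_pairs(name: str) -> list[tuple[int, int]]:
    """Named (acidic, basic) residue pair set, author numbering."""
    cfgs = _load("saltbridge_pairs.yaml")
    if name not in cfgs:
        raise KeyError(f"unknown salt-bridge set {name!r}; available: {sorted(cfgs)}")
    return [tuple(pair) for pair in cfgs[name]]


def binding_defaults() -> dict:
    return dict(_load("binding.yaml"))


def permeability_defaults() -> dict:
    return dict(_load("permeability_defaults.yaml"))
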