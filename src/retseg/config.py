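"""Configuration: the pipeline's manually tunable parameters, with hard bounds.

Nine parameters govern the segmentation and each is range-validated against
its documented operating interval.  Precedence is defaults < YAML file <
explicit overrides (CLI flags); unknown keys are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import yaml

log = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "ResolvedConfig", "load_config"]

DEFAULTS: dict = {
    "preprocess.tophat_radius": 30,
    "fov.sobel_threshold": "auto",
    "texture.levels": 3,
    "texture.k": 8,
    "texture.hminima": 0.05,
    "texture.presmooth_radius": 4,
    "texture.override": None,
    "enhance.sigma": 1.5,
    "enhance.beta": 0.5,
    "enhance.c": "auto",
    "entropy.L": 255,
    "entropy.mask_scale": 0.5,
    "entropy.reflex_scale": 1.5,
    "entropy.reflex_channel": "green",
    "segment.min_fine": 5,
    "segment.min_coarse": 16,
    "segment.global_threshold": 0.1,
    "segment.class2_reflex": True,
    "segment.reflex_dilation": 4,
    "width.gap_tolerance": 0,
    "seed": 0,
}

# (lo, hi) inclusive numeric bounds; None = unbounded on that side
_RANGES: dict = {
    "preprocess.tophat_radius": (10, 60),
    "texture.levels": (2, 5),
    "texture.k": (1, 64),
    "texture.hminima": (1e-9, 1.0),
    "texture.presmooth_radius": (0, 16),
    "enhance.sigma": (0.5, None),
    "enhance.beta": (1e-9, None),
    "entropy.L": (15, 255),
    "entropy.mask_scale": (0.3, 0.8),
    "entropy.reflex_scale": (0.8, 3.0),
    "segment.min_fine": (5, 16),
    "segment.min_coarse": (5, 16),
    "segment.global_threshold": (0.04, 0.2),
    "segment.reflex_dilation": (0, 16),
    "width.gap_tolerance": (0, 10),
}

_CHOICES: dict = {"entropy.reflex_channel": ("green", "luma")}


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved parameter record with per-key provenance."""

    values: dict
    provenance: dict  # key -> "default" | "file" | "flag"

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


def _validate(key: str, value) -> None:
    if key in _CHOICES and value not in _CHOICES[key]:
        raise ValueError(f"{key}={value!r}: must be one of {_CHOICES[key]}")
    if key in _RANGES and not (isinstance(value, str) and value == "auto"):
        lo, hi = _RANGES[key]
        if lo is not None and value < lo:
            raise ValueError(f"{key}={value}: below allowed minimum {lo}")
        if hi is not None and value > hi:
            raise ValueError(f"{key}={value}: above allowed maximum {hi}")


def _flatten(d: dict, prefix: str = "") -> dict:
    """Flatten nested YAML sections to dotted keys; a dict value whose
    dotted key is itself a config key (e.g. texture.override) stays whole."""
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict) and key not in DEFAULTS:
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> ResolvedConfig:
    """Resolve the configuration: defaults < YAML file < overrides."""
    values = dict(DEFAULTS)
    prov = {k: "default" for k in DEFAULTS}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path!r} is not a mapping")
        for k, v in _flatten(raw).items():
            if k not in DEFAULTS:
                raise ValueError(f"unknown config key {k!r}")
            values[k], prov[k] = v, "file"
    for k, v in (overrides or {}).items():
        if k not in DEFAULTS:
            raise ValueError(f"unknown config key {k!r}")
        values[k], prov[k] = v, "flag"
    for k, v in values.items():
        if v is not None:
            _validate(k, v)
    if values["segment.min_fine"] > values["segment.min_coarse"]:
        raise ValueError("segment.min_fine must be ≤ segment.min_coarse")
    for k in sorted(values):
        if prov[k] != "default":
            log.info("config %s = %r (%s)", k, values[k], prov[k])
    return ResolvedConfig(values=values, provenance=prov)
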