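"""Configuration loading, merging and fingerprinting.

The package ships a complete default configuration (``data/default.yaml``)
holding every membrane, timing and mechanical parameter, so the standard
simulations need no flags.  A user file is deep-merged over the defaults.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["default_config", "load_config", "config_fingerprint"]


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def default_config() -> dict[str, Any]:
    """The shipped default configuration as a nested dict."""
    text = resources.files("sacgen.data").joinpath("default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults, optionally deep-merged with a user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def config_fingerprint(cfg: Mapping[str, Any]) -> str:
    """Stable hash identifying a configuration (for run reports)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
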