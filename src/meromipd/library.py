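"""Bundled model library: the 18 literature-derived configuration files.

Each YAML document carries the published typical values and covariate names
of one adult-ICU meropenem population-PK model.  Covariate relation forms
and variance components are approximate placeholders (the exact published
equations live in the original articles); every config says so in its
``source_note``.  Fully specified synthetic models — not these — are used
wherever a test needs known variances.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Union

from .modelspec import ModelSpec, load_model

__all__ = ["bundled_model_dir", "bundled_models", "load_model_dir"]


def bundled_model_dir() -> Path:
    """Directory holding the bundled model configuration files."""
    return Path(resources.files("meromipd") / "models")


def load_model_dir(path: Union[str, Path]) -> Dict[str, ModelSpec]:
    """Load every ``*.yaml`` model config under ``path``, keyed by model name."""
    specs = {}
    for f in sorted(Path(path).glob("*.yaml")):
        spec = load_model(f)
        specs[spec.name] = spec
    return specs


def bundled_models() -> Dict[str, ModelSpec]:
    """The 18 bundled literature-derived model specifications."""
    return load_model_dir(bundled_model_dir())
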