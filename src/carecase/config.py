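"""Configuration loading, validation and serialization.

Parameter sets live in human-editable YAML files, one per parameter table
(mammography, asthma, economics), each annotated with provenance comments.
A ``kind`` key selects the schema; everything else is validated by the
corresponding pydantic model — unknown keys are rejected and out-of-range
probabilities raise errors naming the offending field.  Packaged defaults
reproduce the published base case field for field.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel

from .asthma import AsthmaParams
from .economics import EconomicAssumptions
from .mammography import MammographyParams

__all__ = [
    "load_params", "dump_params", "default_config_path", "config_hash",
    "load_mammography_params", "load_asthma_params", "load_economic_assumptions",
]

_SCHEMAS: dict[str, type[BaseModel]] = {
    "mammography": MammographyParams,
    "asthma": AsthmaParams,
    "economics": EconomicAssumptions,
}
_DEFAULT_FILES = {
    "mammography": "mammography.yaml",
    "asthma": "asthma.yaml",
    "economics": "economics.yaml",
}


def default_config_path(kind: str) -> Path:
    """Path of the packaged default configuration for ``kind``."""
    if kind not in _DEFAULT_FILES:
        raise ValueError(f"unknown config kind {kind!r}; expected one of {sorted(_DEFAULT_FILES)}")
    return Path(str(resources.files("carecase").joinpath("configs", _DEFAULT_FILES[kind])))


def load_params(path: str | Path) -> MammographyParams | AsthmaParams | EconomicAssumptions:
    """Load and validate a parameter file.

    The file must carry a top-level ``kind`` key (``mammography``, ``asthma``
    or ``economics``); all other keys are schema-validated parameters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ValueError(f"{path}: parameter file must be a mapping with a 'kind' key")
    kind = raw.pop("kind")
    if kind not in _SCHEMAS:
        raise ValueError(f"{path}: unknown kind {kind!r}; expected one of {sorted(_SCHEMAS)}")
    return _SCHEMAS[kind](**raw)


def dump_params(params: MammographyParams | AsthmaParams | EconomicAssumptions,
                path: str | Path) -> None:
    """Serialize a parameter set back to YAML (round-trips with load_params)."""
    for kind, schema in _SCHEMAS.items():
        if isinstance(params, schema):
            break
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    payload = {"kind": kind, **json.loads(params.model_dump_json())}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_hash(params: BaseModel) -> str:
    """Stable SHA-256 over the full-precision parameter values."""
    blob = params.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()


def _load_default(kind: str, path: str | Path | None):
    if path is None:
        path = default_config_path(kind)
    params = load_params(path)
    expected = _SCHEMAS[kind]
    if not isinstance(params, expected):
        raise TypeError(f"{path} holds {type(params).__name__}, expected {expected.__name__}")
    return params


def load_mammography_params(path: str | Path | None = None) -> MammographyParams:
    """Mammography parameters from ``path`` or the packaged base case."""
    return _load_default("mammography", path)


def load_asthma_params(path: str | Path | None = None) -> AsthmaParams:
    """Asthma parameters from ``path`` or the packaged base case."""
    return _load_default("asthma", path)


def load_economic_assumptions(path: str | Path | None = None) -> EconomicAssumptions:
    """Economic assumptions from ``path`` or the packaged defaults."""
    return _load_default("economics", path)
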