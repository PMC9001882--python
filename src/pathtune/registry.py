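"""Named parameter-set registry with YAML (de)serialization.

The numeric kinetic values shipped here are the package's documented
defaults, calibrated so each closed loop shows the qualitative behavior
the models were built to study: a steady product level with partial
recovery after a 60% step loss of the secondary substrate (merging), and
the full naringenin system settling near a 1 g/L titer with the
sigma/CHS transient response to a malonyl-CoA drop.  Every field carries
the units stated in the parameter dataclasses (molecules per cell,
minutes).  Entries can be overridden from user YAML/JSON files.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Tuple

import yaml

from .models import MODELS
from .models.merging import MergingParams
from .models.naringenin import (
    AhlParams,
    ActuatorParams,
    BiosensorParams,
    ControllerParams,
    GlobalParams,
    MetabolicParams,
    NaringeninParams,
)

_GROUPS = {
    "metabolic": MetabolicParams,
    "biosensor": BiosensorParams,
    "controller": ControllerParams,
    "actuator": ActuatorParams,
    "ahl": AhlParams,
    "global": GlobalParams,
}

BUILTIN = ("merging-default", "naringenin-default")


class RegistryError(KeyError):
    """Unknown registry entry or malformed parameter file."""


def available() -> Tuple[str, ...]:
    """Names of the built-in parameter sets."""
    return BUILTIN


def params_from_dict(doc: dict):
    """Build a parameter dataclass from a parsed registry document."""
    try:
        model = doc["model"]
        raw = doc["params"]
    except (KeyError, TypeError) as exc:
        raise RegistryError(f"parameter document missing field: {exc}") from exc
    if model == "merging":
        return MergingParams(**{k: float(v) for k, v in raw.items()})
    if model == "naringenin":
        groups = {}
        for key, cls in _GROUPS.items():
            if key not in raw:
                raise RegistryError(f"naringenin parameter set missing group {key!r}")
            groups["glob" if key == "global" else key] = cls(
                **{k: float(v) for k, v in raw[key].items()}
            )
        return NaringeninParams(**groups)
    raise RegistryError(f"unknown model {model!r} (expected one of {sorted(MODELS)})")


def params_to_dict(params) -> dict:
    """Serialize a parameter dataclass back to a registry document."""
    if isinstance(params, MergingParams):
        return {"model": "merging", "params": dataclasses.asdict(params)}
    if isinstance(params, NaringeninParams):
        raw = {
            key: dataclasses.asdict(getattr(params, "glob" if key == "global" else key))
            for key in _GROUPS
        }
        return {"model": "naringenin", "params": raw}
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def load(name_or_path: str):
    """Load a parameter set by registry name or from a YAML/JSON file path.

    Returns ``(model_name, params)``.
    """
    name = str(name_or_path)
    if name in BUILTIN:
        ref = importlib.resources.files("pathtune") / "registry_data" / f"{name}.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        path = Path(name)
        if not path.exists():
            raise RegistryError(
                f"{name!r} is neither a built-in registry entry {BUILTIN} "
                "nor an existing parameter file"
            )
        doc = yaml.safe_load(path.read_text())
    params = params_from_dict(doc)
    return doc["model"], params


def save(params, path: str | Path) -> None:
    """Write a parameter set as a registry-style YAML file."""
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def default_params(model_name: str):
    """The built-in default parameter set for a model."""
    if model_name not in MODELS:
        raise RegistryError(f"unknown model {model_name!r}")
    return load(f"{model_name}-default")[1]
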