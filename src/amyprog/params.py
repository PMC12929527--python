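"""Hierarchical, unit-annotated parameter store.

All kinetic parameters of the simulator live in one nested mapping,
serialised as YAML. Concentrations are nanomolar (nM), volumes mL,
flows mL/h, first-order rate constants 1/h, zero-order rates nM/h.
Simulation time is hours; one year of age is 8766 h.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Any, Iterator, Mapping

import yaml

#: hours per year of age (365.25 days)
HOURS_PER_YEAR = 8766.0

#: seconds -> hours conversion for rate constants printed per second
PER_SECOND_TO_PER_HOUR = 3600.0


class ParameterError(KeyError):
    """A referenced parameter is missing from the set."""


class ParameterSet:
    """Nested parameter mapping with dotted-path access.

    Parameters are looked up with paths like ``"transport.flows.Q_Bi"``.
    The object is mutable (calibration rewrites entries) but cheap to
    copy, and hashes its canonical JSON form so runs can record exactly
    which parameterisation produced them.
    """

    def __init__(self, data: Mapping[str, Any]):
        self._data: dict[str, Any] = copy.deepcopy(dict(data))

    # -- construction -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path!r} does not contain a mapping")
        return cls(data)

    @classmethod
    def defaults(cls) -> "ParameterSet":
        """The shipped, calibration-passing default parameter set."""
        ref = resources.files("amyprog").joinpath("data/defaults.yaml")
        data = yaml.safe_load(ref.read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError("bundled defaults.yaml is corrupted")
        return cls(data)

    # -- access -------------------------------------------------------
    def get(self, path: str, default: Any = ParameterError) -> Any:
        node: Any = self._data
        for part in path.split("."):
            if not isinstance(node, Mapping) or part not in node:
                if default is ParameterError:
                    raise ParameterError(f"missing parameter {path!r}")
                return default
            node = node[part]
        return node

    def set(self, path: str, value: Any) -> None:
        parts = path.split(".")
        node = self._data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ParameterError(f"cannot descend into scalar at {part!r}")
        node[parts[-1]] = value

    def section(self, path: str) -> dict:
        sec = self.get(path)
        if not isinstance(sec, Mapping):
            raise ParameterError(f"{path!r} is not a parameter section")
        return copy.deepcopy(dict(sec))

    def __getitem__(self, path: str) -> Any:
        return self.get(path)

    def __contains__(self, path: str) -> bool:
        try:
            self.get(path)
            return True
        except ParameterError:
            return False

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    # -- bookkeeping --------------------------------------------------
    def copy(self) -> "ParameterSet":
        return ParameterSet(self._data)

    def to_dict(self) -> dict:
        return copy.deepcopy(self._data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self._data, fh, sort_keys=True)

    def hash(self) -> str:
        """SHA-256 of the canonical JSON form, for provenance records."""
        blob = json.dumps(self._data, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParameterSet(sections={sorted(self._data)}, hash={self.hash()[:8]})"
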