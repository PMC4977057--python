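"""Biological-process model definitions: named, weighted groups of assays.

A *process model* maps a biological process (e.g. adipocyte differentiation)
to an ordered list of *slices*; each slice pools one or more assay endpoints
targeting the same gene or gene family, and carries a proportional weight.
Under the default equal weighting every slice weighs ``1 / n_slices``, so the
weights always sum to 1 and the overall score stays on a 0-1 scale.

Six bundled models cover metabolic-disruption processes (adipocyte
differentiation; feeding behavior in rodents and in C. elegans; insulin
sensitivity in peripheral tissue; islet cell function; beta cell function),
with slice counts 5, 9, 12, 11, 11 and 14.  A seventh, single-slice
companion model scores retinoic acid receptor (RAR) activity, reported
alongside the adipocyte model because RAR agonism can block adipogenic
signalling downstream and therefore changes the interpretation of a high
adipocyte-differentiation score.

Bundled assay identifiers are ``<GENE>_<k>`` placeholders derived from the
per-gene assay counts of the published model tables; users screening a real
release supply their own JSON with the release's endpoint names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .hts import HTSMatrix

__all__ = [
    "SliceDef",
    "ProcessModel",
    "ModelValidationError",
    "PanelReport",
    "load_model",
    "write_model",
    "bundled_models",
    "bundled_model",
    "rar_model",
    "validate_against_panel",
    "BUNDLED_MODEL_NAMES",
]

#: bundled model names, in the order of the published table
BUNDLED_MODEL_NAMES = (
    "adipocyte_differentiation",
    "feeding_behavior_rodent",
    "feeding_behavior_celegans",
    "insulin_sensitivity",
    "islet_cell_function",
    "beta_cell_function",
)

_WEIGHT_SUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """A model definition violates its invariants."""


@dataclass(frozen=True)
class SliceDef:
    """One slice: a named, weighted pool of assay endpoints."""

    slice_name: str
    assay_ids: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if not self.assay_ids:
            raise ModelValidationError(f"slice {self.slice_name!r} has no assays")
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise ModelValidationError(f"slice {self.slice_name!r} has duplicate assay ids")
        if not self.weight > 0:
            raise ModelValidationError(f"slice {self.slice_name!r} weight must be positive")


@dataclass(frozen=True)
class ProcessModel:
    """A named, ordered collection of slices whose weights sum to 1."""

    model_name: str
    slices: tuple[SliceDef, ...]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ModelValidationError(f"model {self.model_name!r} has no slices")
        names = [s.slice_name for s in self.slices]
        if len(set(names)) != len(names):
            raise ModelValidationError(f"model {self.model_name!r} has duplicate slice names")
        total = sum(s.weight for s in self.slices)
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ModelValidationError(
                f"model {self.model_name!r} slice weights sum to {total!r}, expected 1"
            )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def slice_names(self) -> list[str]:
        return [s.slice_name for s in self.slices]

    @property
    def assay_ids(self) -> list[str]:
        """All assay ids referenced by the model (order-preserving, unique)."""
        seen: dict[str, None] = {}
        for s in self.slices:
            for aid in s.assay_ids:
                seen.setdefault(aid)
        return list(seen)


def _model_from_dict(doc: dict) -> ProcessModel:
    try:
        name = doc["model_name"]
        raw_slices = doc["slices"]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"model definition missing field: {exc}") from exc
    n = len(raw_slices)
    if n == 0:
        raise ModelValidationError(f"model {name!r} defines no slices")
    explicit = [s.get("weight") for s in raw_slices]
    if any(w is not None for w in explicit) and any(w is None for w in explicit):
        raise ModelValidationError(
            f"model {name!r}: weights must be given for all slices or none"
        )
    slices = tuple(
        SliceDef(
            slice_name=s["slice_name"],
            assay_ids=tuple(s["assay_ids"]),
            weight=float(s["weight"]) if s.get("weight") is not None else 1.0 / n,
        )
        for s in raw_slices
    )
    return ProcessModel(name, slices)


def load_model(path) -> ProcessModel:
    """Load a model-definition JSON; omitted weights default to equal."""
    with open(path, encoding="utf-8") as fh:
        return _model_from_dict(json.load(fh))


def model_to_dict(model: ProcessModel) -> dict:
    return {
        "model_name": model.model_name,
        "slices": [
            {"slice_name": s.slice_name, "assay_ids": list(s.assay_ids), "weight": s.weight}
            for s in model.slices
        ],
    }


def write_model(model: ProcessModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def _load_bundled(name: str) -> ProcessModel:
    ref = resources.files("toxscreen.data.models").joinpath(name + ".json")
    return _model_from_dict(json.loads(ref.read_text(encoding="utf-8")))


def bundled_models() -> list[ProcessModel]:
    """The six bundled biological-process models (RAR companion excluded)."""
    return [_load_bundled(name) for name in BUNDLED_MODEL_NAMES]


def bundled_model(name: str) -> ProcessModel:
    if name == "rar_score":
        return rar_model()
    if name not in BUNDLED_MODEL_NAMES:
        raise KeyError(
            f"unknown bundled model {name!r}; choose from {BUNDLED_MODEL_NAMES} or 'rar_score'"
        )
    return _load_bundled(name)


def rar_model() -> ProcessModel:
    """Single-slice retinoic acid receptor companion model."""
    return _load_bundled("rar_score")


@dataclass(frozen=True)
class PanelReport:
    """Which model assays a panel resolves; missing assays are legal (sparse data)."""

    model_name: str
    resolved: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def fully_resolved(self) -> bool:
        return not self.missing


def validate_against_panel(model: ProcessModel, matrix: HTSMatrix) -> PanelReport:
    """Report which of the model's assay ids are present in the matrix panel."""
    panel = set(matrix.assay_ids)
    resolved = tuple(a for a in model.assay_ids if a in panel)
    missing = tuple(a for a in model.assay_ids if a not in panel)
    return PanelReport(model.model_name, resolved, missing)
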