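"""Tube geometry, flow/velocity conversion and the four-setting registry.

The phantom experiments use straight glass tubes of known inner diameter;
under steady laminar flow the volumetric flow rate ``Q`` set at the flow
meter and the mean velocity ``v`` inside the tube are linked by the
volumetric-flow relation ``Q = v * A`` with ``A = pi * d**2 / 4`` the lumen
cross-section.  The public API speaks the units the flow meter and the
result tables use — mm for diameters, ml/min for flows, cm/s for
velocities — and converts internally.

The four canonical settings of the stenosis experiment (rest, hyperaemic
healthy, hyperaemic stenotic, doubled-power stenotic) ship as a packaged
YAML registry; :func:`canonical_settings` loads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

from .errors import DomainError, InvalidGeometryError

__all__ = [
    "Stenosis",
    "TubeGeometry",
    "SettingRole",
    "FlowSetting",
    "cross_section_area",
    "flow_to_velocity",
    "velocity_to_flow",
    "canonical_settings",
    "load_settings",
]

_MM_PER_CM = 10.0
_S_PER_MIN = 60.0

#: Longitudinal drive-field field-of-view extent used by default (mm).
DEFAULT_FOV_LENGTH_MM = 22.4


@dataclass(frozen=True)
class Stenosis:
    """A centred cylindrical stenosis insert."""

    min_lumen_mm: float
    length_mm: float


@dataclass(frozen=True)
class TubeGeometry:
    """A straight tube segment imaged along its axis.

    Parameters
    ----------
    inner_diameter_mm
        Nominal inner diameter of the (non-stenotic part of the) tube.
    fov_length_mm
        Longitudinal extent ``s`` of the field of view; enters the FDHM
        velocity formula ``v = c * s / FDHM``.
    stenosis
        Optional stenosis insert.  Conversion between flow and velocity
        always uses the nominal diameter because the field of view sits in
        the laminar region away from the insert.
    """

    inner_diameter_mm: float
    fov_length_mm: float = DEFAULT_FOV_LENGTH_MM
    stenosis: Stenosis | None = None

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0:
            raise InvalidGeometryError(
                f"inner_diameter_mm must be > 0, got {self.inner_diameter_mm}"
            )
        if self.fov_length_mm <= 0:
            raise InvalidGeometryError(
                f"fov_length_mm must be > 0, got {self.fov_length_mm}"
            )
        if self.stenosis is not None:
            if self.stenosis.min_lumen_mm >= self.inner_diameter_mm:
                raise InvalidGeometryError(
                    "stenosis min lumen must be smaller than the tube diameter"
                )

    @property
    def area_cm2(self) -> float:
        """Nominal lumen cross-section in cm**2."""
        return cross_section_area(self.inner_diameter_mm)

    @property
    def fov_length_cm(self) -> float:
        return self.fov_length_mm / _MM_PER_CM


class SettingRole(str, Enum):
    REST = "rest"
    HYPERAEMIA_HEALTHY = "hyperaemia_healthy"
    HYPERAEMIA_STENOSIS = "hyperaemia_stenosis"
    DOUBLE_HYPERAEMIA_STENOSIS = "double_hyperaemia_stenosis"


@dataclass(frozen=True)
class FlowSetting:
    """One state of the circulation phantom.

    ``reference_flow_ml_min`` is the flow-meter ground truth and
    ``flow_sd_ml_min`` its reported measurement uncertainty;
    ``reference_velocity_cm_s`` is the rounded tabulated velocity, which
    must agree with ``flow_to_velocity`` within printing precision.
    """

    id: int
    geometry: TubeGeometry
    reference_flow_ml_min: float
    flow_sd_ml_min: float
    reference_velocity_cm_s: float
    role: SettingRole

    @property
    def computed_velocity_cm_s(self) -> float:
        """Velocity implied by the reference flow and nominal diameter."""
        return flow_to_velocity(
            self.reference_flow_ml_min, self.geometry.inner_diameter_mm
        )


def cross_section_area(diameter_mm: float) -> float:
    """Lumen cross-section ``pi * d**2 / 4`` in cm**2 for ``d`` in mm."""
    if diameter_mm <= 0:
        raise InvalidGeometryError(f"diameter must be > 0, got {diameter_mm}")
    d_cm = diameter_mm / _MM_PER_CM
    return math.pi * d_cm * d_cm / 4.0


def flow_to_velocity(flow_ml_min: float, diameter_mm: float) -> float:
    """Mean velocity (cm/s) from volumetric flow (ml/min): ``v = Q / A``."""
    if flow_ml_min < 0:
        raise DomainError(f"flow must be >= 0, got {flow_ml_min}")
    area = cross_section_area(diameter_mm)
    return flow_ml_min / _S_PER_MIN / area


def velocity_to_flow(velocity_cm_s: float, diameter_mm: float) -> float:
    """Volumetric flow (ml/min) from mean velocity (cm/s): ``Q = v * A``."""
    if velocity_cm_s < 0:
        raise DomainError(f"velocity must be >= 0, got {velocity_cm_s}")
    area = cross_section_area(diameter_mm)
    return velocity_cm_s * area * _S_PER_MIN


def _setting_from_mapping(entry: dict, fov_length_mm: float) -> FlowSetting:
    sten = entry.get("stenosis")
    stenosis = (
        Stenosis(float(sten["min_lumen_mm"]), float(sten["length_mm"]))
        if sten
        else None
    )
    geometry = TubeGeometry(
        inner_diameter_mm=float(entry["diameter_mm"]),
        fov_length_mm=float(entry.get("fov_length_mm", fov_length_mm)),
        stenosis=stenosis,
    )
    return FlowSetting(
        id=int(entry["id"]),
        geometry=geometry,
        reference_flow_ml_min=float(entry["flow_ml_min"]),
        flow_sd_ml_min=float(entry.get("flow_sd_ml_min", 0.0)),
        reference_velocity_cm_s=float(entry["reference_velocity_cm_s"]),
        role=SettingRole(entry["role"]),
    )


def load_settings(path: str | Path) -> list[FlowSetting]:
    """Load a settings registry from a YAML file.

    The file holds ``fov_length_mm`` and a ``settings`` list with keys
    ``id``, ``diameter_mm``, ``flow_ml_min``, ``flow_sd_ml_min``,
    ``reference_velocity_cm_s``, ``role`` and an optional ``stenosis``
    mapping.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _settings_from_doc(doc)


def _settings_from_doc(doc: dict) -> list[FlowSetting]:
    fov = float(doc.get("fov_length_mm", DEFAULT_FOV_LENGTH_MM))
    settings = [_setting_from_mapping(e, fov) for e in doc["settings"]]
    ids = [s.id for s in settings]
    if len(set(ids)) != len(ids):
        raise InvalidGeometryError(f"duplicate setting ids: {ids}")
    return settings


def canonical_settings(fov_length_mm: float | None = None) -> list[FlowSetting]:
    """The four packaged settings of the stenosis-phantom experiment.

    Setting 1 is a 4 mm tube at resting flow (151 ml/min, ~20 cm/s);
    setting 2 a 6 mm tube at hyperaemic flow (680 ml/min, ~40 cm/s);
    setting 3 the 6 mm tube with a 1.5 mm stenosis at the same pump power
    (205 ml/min, ~12 cm/s); setting 4 doubles the pump power of setting 3
    (410 ml/min, ~24 cm/s).
    """
    text = resources.files("mpiflow.data").joinpath("settings.yaml").read_text()
    doc = yaml.safe_load(text)
    if fov_length_mm is not None:
        doc["fov_length_mm"] = fov_length_mm
    return _settings_from_doc(doc)
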