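"""Coronary flow reserve, fractional flow reserve and agreement statistics.

CFR is the factor by which flow can rise on demand: the ratio of maximal
(hyperaemic, dilated) flow to resting flow, about 5 in healthy vessels.
FFR quantifies what a stenosis costs: the ratio of the maximal flow
achievable with the stenosis present to the theoretical maximal flow
without it; values below ~0.75-0.8 indicate a treatment-relevant lesion.

In the four-setting phantom, setting 1 provides the resting flow
``Q_norm``, setting 2 the theoretical maximal flow ``Q_max``, and the
stenotic settings 3/4 provide ``Q_sten``; image-derived mean velocities
are converted to flows through the nominal tube cross-section before
forming the ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DomainError
from .geometry import FlowSetting, SettingRole, velocity_to_flow

__all__ = [
    "CFRResult",
    "CFRComparison",
    "AgreementStats",
    "cfr",
    "ffr",
    "cfr_experiment",
    "agreement",
]


def cfr(q_flow_ml_min: float, q_norm_ml_min: float) -> float:
    """Flow reserve ratio ``Q / Q_norm``."""
    if q_norm_ml_min <= 0:
        raise DomainError(f"Q_norm must be > 0, got {q_norm_ml_min}")
    return q_flow_ml_min / q_norm_ml_min


def ffr(q_sten_ml_min: float, q_max_ml_min: float) -> float:
    """Fractional flow reserve ``Q_sten / Q_max``."""
    if q_max_ml_min <= 0:
        raise DomainError(f"Q_max must be > 0, got {q_max_ml_min}")
    return q_sten_ml_min / q_max_ml_min


@dataclass
class CFRResult:
    """Flows and reserve ratios for one stenotic setting."""

    q_norm_ml_min: float
    q_max_ml_min: float
    q_sten_ml_min: float
    cfr: float
    ffr: float
    source: str = "mpi"

    @classmethod
    def from_flows(
        cls, q_norm: float, q_max: float, q_sten: float, source: str = "mpi"
    ) -> "CFRResult":
        return cls(
            q_norm_ml_min=q_norm,
            q_max_ml_min=q_max,
            q_sten_ml_min=q_sten,
            cfr=cfr(q_sten, q_norm),
            ffr=ffr(q_sten, q_max),
            source=source,
        )


@dataclass
class CFRComparison:
    """An image-derived CFR result next to its flow-meter ground truth."""

    setting_id: int
    mpi: CFRResult
    ground_truth: CFRResult
    cfr_abs_dev: float
    cfr_rel_dev: float
    ffr_abs_dev: float
    ffr_rel_dev: float


def cfr_experiment(
    velocities_by_setting: Mapping[int, Sequence[float]],
    settings: Sequence[FlowSetting],
    q_norm_ml_min: float | None = None,
    q_max_ml_min: float | None = None,
) -> dict[int, CFRComparison]:
    """CFR/FFR for each stenotic setting from mean image-derived velocity.

    The mean velocity of a stenotic series is converted to flow through
    the setting's nominal (non-stenotic) diameter; the resting and maximal
    reference flows default to the ground-truth flows of the rest and
    healthy-hyperaemia settings.  Returns, per stenotic setting, the
    image-derived result, the ground-truth result from the flow-meter
    flows, and the absolute/relative deviations of CFR and FFR.
    """
    by_id = {s.id: s for s in settings}
    if q_norm_ml_min is None:
        rest = [s for s in settings if s.role == SettingRole.REST]
        if not rest:
            raise ConfigError("no rest setting available for Q_norm")
        q_norm_ml_min = rest[0].reference_flow_ml_min
    if q_max_ml_min is None:
        healthy = [s for s in settings if s.role == SettingRole.HYPERAEMIA_HEALTHY]
        if not healthy:
            raise ConfigError("no healthy-hyperaemia setting available for Q_max")
        q_max_ml_min = healthy[0].reference_flow_ml_min

    results: dict[int, CFRComparison] = {}
    for setting_id, velocities in velocities_by_setting.items():
        if setting_id not in by_id:
            raise ConfigError(f"setting {setting_id} not in the registry")
        setting = by_id[setting_id]
        if setting.geometry.stenosis is None:
            continue
        velocities = np.asarray(velocities, dtype=float)
        if velocities.size == 0:
            raise ConfigError(f"no velocities supplied for setting {setting_id}")
        q_sten = velocity_to_flow(
            float(velocities.mean()), setting.geometry.inner_diameter_mm
        )
        mpi = CFRResult.from_flows(q_norm_ml_min, q_max_ml_min, q_sten, source="mpi")
        gt = CFRResult.from_flows(
            q_norm_ml_min,
            q_max_ml_min,
            setting.reference_flow_ml_min,
            source="ground_truth",
        )
        results[setting_id] = CFRComparison(
            setting_id=setting_id,
            mpi=mpi,
            ground_truth=gt,
            cfr_abs_dev=abs(mpi.cfr - gt.cfr),
            cfr_rel_dev=abs(mpi.cfr - gt.cfr) / gt.cfr,
            ffr_abs_dev=abs(mpi.ffr - gt.ffr),
            ffr_rel_dev=abs(mpi.ffr - gt.ffr) / gt.ffr,
        )
    return results


@dataclass
class AgreementStats:
    """Pearson agreement of estimated vs reference velocities."""

    pearson_r: float
    p_value: float
    mean_abs_rel_error: float
    n: int


def agreement(
    estimates: Sequence[float], references: Sequence[float]
) -> AgreementStats:
    """Pearson r (two-sided p) and mean absolute relative error."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise DomainError("estimate and reference vectors differ in length")
    if est.size < 2:
        raise DomainError("agreement needs at least two pairs")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise DomainError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(est, ref)
    mare = float(np.mean(np.abs(est - ref) / ref))
    return AgreementStats(
        pearson_r=float(r), p_value=float(p), mean_abs_rel_error=mare, n=est.size
    )
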