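"""Deterministic risk evaluation for one tissue-parameter set.

Given a co-registered voxel model, this module produces per-voxel RED
maps, per-organ excess absolute risk

    EAR_org = mu * beta_EAR * (1/N_org) * sum_i RED_i ,

whole-patient totals (the sum over modelled organs), relative EAR between
two plans on the same anatomy (per organ: a plain ratio of summed RED,
since beta and mu cancel; for totals: a ratio of summed organ EARs, which
does not reduce to a RED ratio), the linear-no-threshold variant
(RED replaced by dose), and integral dose (dose x voxel volume).

Organs on the roster that are absent from a plan's grid, or excluded from
the risk model (spleen), are reported as absent rather than zero risk —
exclusion and zero risk are semantically distinct.  Zero-risk tissues
(heart, vessels) contribute exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_models import (
    EXCLUDED_ORGANS,
    FractionationContext,
    InvalidInputError,
    ModelKind,
    TissueParams,
    red_carcinoma_values,
    red_sarcoma_values,
)
from .plan_io import UNLABELLED, VoxelModel


@dataclass(frozen=True)
class OrganEAR:
    """Risk summary for one organ under one parameter set.

    ``ear`` in (10,000 person-years)^-1; ``sum_red``/``mean_dose`` in Gy;
    ``integral_dose`` in Gy cm^3.
    """

    organ_name: str
    ear: float
    n_voxels: int
    sum_red: float
    mean_dose: float
    integral_dose: float


@dataclass(frozen=True)
class PatientEAR:
    """Per-organ risks plus their sum for one plan."""

    organs: tuple[OrganEAR, ...]
    total_ear: float
    modality: str

    def organ(self, name: str) -> OrganEAR:
        for o in self.organs:
            if o.organ_name == name:
                return o
        raise KeyError(name)


def voxel_red_map(
    model: VoxelModel,
    tissue_library: dict[str, TissueParams],
    ctx: FractionationContext,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Per-voxel RED field [Gy] using each tissue's own dose-response model.

    ``overrides`` maps organ name to a sampled ``(alpha, R)`` pair, used by
    the Monte Carlo study in place of the library means.  Unlabelled voxels
    and excluded organs carry RED 0; zero-risk tissues carry exactly 0.
    A label that is neither in the library nor excluded is an error.
    """
    red = np.zeros(model.grid.dims, dtype=float)
    for name in model.present_organs:
        if name in EXCLUDED_ORGANS:
            continue
        if name not in tissue_library:
            raise InvalidInputError(f"no tissue parameters for label {name!r}")
        params = tissue_library[name]
        if params.model_kind is ModelKind.ZERO_RISK:
            continue
        mask = model.organ_mask(name)
        dose = model.dose[mask]
        alpha, R = (
            overrides[name] if overrides and name in overrides
            else (params.alpha, params.repopulation_R)
        )
        fn = (
            red_carcinoma_values
            if params.model_kind is ModelKind.CARCINOMA
            else red_sarcoma_values
        )
        red[mask] = fn(dose, alpha, R, ctx, params.alpha_beta_ratio)
    return red


def organ_ear(
    red_field: np.ndarray,
    model: VoxelModel,
    organ: str,
    beta_ear: float,
    mu: float = 1.0,
) -> OrganEAR | None:
    """EAR of one organ: ``mu * beta_EAR * mean(RED over organ voxels)``.

    Returns None when the organ has no voxels in this plan (absent, not
    zero-risk).
    """
    if organ not in model.label_names:
        return None
    mask = model.organ_mask(organ)
    n = int(mask.sum())
    if n == 0:
        return None
    sum_red = float(red_field[mask].sum())
    dose = model.dose[mask]
    return OrganEAR(
        organ_name=organ,
        ear=mu * beta_ear * sum_red / n,
        n_voxels=n,
        sum_red=sum_red,
        mean_dose=float(dose.mean()),
        integral_dose=float(dose.sum() * model.grid.voxel_volume),
    )


def ear_linear(
    model: VoxelModel,
    organ: str,
    beta_ear: float,
    mu: float = 1.0,
) -> OrganEAR | None:
    """Linear-no-threshold organ EAR: ``mu * beta_EAR * mean dose``."""
    return organ_ear(model.dose, model, organ, beta_ear, mu)


def total_ear(organs, modality: str = "other") -> PatientEAR:
    """Sum organ EARs into a patient total.  Absent organs (None) drop out."""
    kept = tuple(o for o in organs if o is not None)
    names = [o.organ_name for o in kept]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate organs in the patient roster")
    return PatientEAR(
        organs=kept,
        total_ear=float(sum(o.ear for o in kept)),
        modality=str(modality),
    )


def rel_ear_organ(
    red_field_plan1: np.ndarray,
    red_field_plan2: np.ndarray,
    model: VoxelModel,
    organ: str,
) -> float:
    """Organ relative EAR of plan 1 vs plan 2: the ratio of summed RED.

    beta_EAR and mu are identical for both plans over one organ, so they
    cancel.  Requires both plans on the same anatomy (the shared ``model``
    label field) and a nonzero denominator.
    """
    mask = model.organ_mask(organ)
    denom = float(red_field_plan2[mask].sum())
    if denom == 0.0:
        raise ZeroDivisionError(
            f"relative EAR undefined for {organ!r}: reference plan has zero RED"
        )
    return float(red_field_plan1[mask].sum()) / denom


def rel_ear_total(plan1: PatientEAR, plan2: PatientEAR) -> float:
    """Whole-patient relative EAR: ratio of the organ-EAR sums.

    Unlike the organ-level ratio this does not reduce to a RED ratio,
    because each organ carries its own beta_EAR weight.
    """
    if plan2.total_ear == 0.0:
        raise ZeroDivisionError("relative EAR undefined: reference plan has zero total EAR")
    return plan1.total_ear / plan2.total_ear


def integral_dose(model: VoxelModel, scope: str | None = None) -> float:
    """Integral dose [Gy cm^3]: sum of voxel dose times voxel volume.

    ``scope`` is an organ name, or None for every labelled (in-patient)
    voxel.
    """
    if scope is None:
        mask = model.labels > 0
    else:
        mask = model.organ_mask(scope)
    return float(model.dose[mask].sum() * model.grid.voxel_volume)


def evaluate_plan(
    model: VoxelModel,
    tissue_library: dict[str, TissueParams],
    ctx: FractionationContext,
    mu: float = 1.0,
    roster=None,
    dose_response: str = "full",
    overrides: dict[str, tuple[float, float]] | None = None,
    beta_overrides: dict[str, float] | None = None,
) -> PatientEAR:
    """Evaluate one plan end to end: RED map, organ EARs, total.

    ``dose_response`` is "full" (mechanistic RED) or "linear" (RED = D).
    Roster organs that are excluded or absent are skipped; zero-risk organs
    are reported with EAR exactly 0.
    """
    if dose_response not in ("full", "linear"):
        raise InvalidInputError("dose_response must be 'full' or 'linear'")
    roster = tuple(roster) if roster is not None else model.present_organs
    red = (
        model.dose
        if dose_response == "linear"
        else voxel_red_map(model, tissue_library, ctx, overrides)
    )
    organs = []
    for name in roster:
        if name in EXCLUDED_ORGANS or name == UNLABELLED:
            continue
        if name not in tissue_library:
            raise InvalidInputError(f"no tissue parameters for organ {name!r}")
        params = tissue_library[name]
        if params.model_kind is ModelKind.ZERO_RISK:
            if name in model.label_names and model.organ_voxel_count(name) > 0:
                mask = model.organ_mask(name)
                organs.append(
                    OrganEAR(
                        organ_name=name,
                        ear=0.0,
                        n_voxels=int(mask.sum()),
                        sum_red=0.0,
                        mean_dose=float(model.dose[mask].mean()),
                        integral_dose=float(
                            model.dose[mask].sum() * model.grid.voxel_volume
                        ),
                    )
                )
            continue
        beta = (
            beta_overrides[name]
            if beta_overrides and name in beta_overrides
            else params.beta_ear
        )
        if dose_response == "linear":
            o = ear_linear(model, name, beta, mu)
        else:
            o = organ_ear(red, model, name, beta, mu)
        if o is not None:
            organs.append(o)
    return total_ear(organs, modality=model.modality.value)


__all__ = [
    "OrganEAR",
    "PatientEAR",
    "ear_linear",
    "evaluate_plan",
    "integral_dose",
    "organ_ear",
    "rel_ear_organ",
    "rel_ear_total",
    "total_ear",
    "voxel_red_map",
]
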