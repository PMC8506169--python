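"""Closed-form risk-equivalent-dose (RED) and excess-absolute-risk (EAR) models.

The dose–response of radiation-induced second cancer is described by
mechanistic models of carcinoma and sarcoma induction that fold
linear-quadratic cell kill and inter-fraction repopulation/repair into a
*risk equivalent dose*::

    RED_carcinoma(D) = e^{-a'D} / (a'R) * (1 - 2R + R^2 e^{a'D}
                                           - (1-R)^2 e^{-a'RD/(1-R)})
    RED_sarcoma(D)   = RED_carcinoma(D) - D e^{-a'D}

with ``a' = alpha + beta*d`` the effective per-fraction cell-kill
coefficient of the linear-quadratic model (``d`` the dose per fraction,
``beta = alpha / (alpha/beta ratio)``), and ``R`` in [0, 1] the
repopulation/repair parameter (0: none between fractions, 1: full
recovery).  RED has the dimension of dose, satisfies ``0 <= RED <= D`` and
reduces to the linear-no-threshold response ``RED -> D`` at low dose.
Excess absolute risk follows as ``EAR = beta_EAR * RED(D) * mu`` where
``beta_EAR`` is the low-dose slope fitted to atomic-bomb-survivor data and
``mu`` an age modifier.

Both RED expressions are indeterminate at R = 0 and R = 1; analytic limit
branches are used for R below ``R_LOW_SWITCH`` and above ``R_HIGH_SWITCH``
(continuity across the switch points is covered by the test suite):

    R -> 0 :  RED_carcinoma -> D e^{-a'D}
    R -> 1 :  RED_carcinoma -> (1 - e^{-a'D}) / a'

All evaluation functions broadcast over numpy arrays; doses are total
physical (or RBE-weighted) voxel doses in Gy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

logger = logging.getLogger("voxear")

#: switch points between the generic bracket and the analytic limit branches
R_LOW_SWITCH = 1e-4
R_HIGH_SWITCH = 1.0 - 1e-4

#: fixed alpha/beta ratio of the linear-quadratic fit, Gy
DEFAULT_ALPHA_BETA_RATIO = 3.0

#: the 13-structure organ roster used for whole-patient bookkeeping
DEFAULT_ORGAN_ROSTER = (
    "breast",
    "oesophagus",
    "heart",
    "liver",
    "lungs",
    "pharynx",
    "spinal_cord",
    "spleen",
    "stomach",
    "thyroid",
    "vessels",
    "bone",
    "soft_tissue",
)

#: organs whose dose-response is considered too uncertain to model at all;
#: reported as excluded ("-"), never as zero risk
EXCLUDED_ORGANS = frozenset({"spleen"})


class ModelKind(str, Enum):
    """Which dose-response family an organ follows."""

    CARCINOMA = "carcinoma"
    SARCOMA = "sarcoma"
    ZERO_RISK = "zero_risk"


class InvalidInputError(ValueError):
    """Raised for out-of-domain doses, ages or model parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Per-organ constants of the RED/EAR models with their uncertainties.

    ``beta_ear`` is in (10,000 person-years Gy)^-1; ``alpha`` in Gy^-1;
    ``repopulation_R`` dimensionless in [0, 1].  Asymmetric beta
    uncertainties are kept as printed and symmetrised on demand.
    """

    organ_name: str
    model_kind: ModelKind
    alpha: float = 0.0
    alpha_sigma: float = 0.0
    repopulation_R: float = 0.0
    R_sigma: float = 0.0
    beta_ear: float = 0.0
    beta_sigma_minus: float = 0.0
    beta_sigma_plus: float = 0.0
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO

    def __post_init__(self) -> None:
        if not 0.0 <= self.repopulation_R <= 1.0:
            raise InvalidInputError(
                f"{self.organ_name}: repopulation_R={self.repopulation_R} outside [0, 1]"
            )
        if self.alpha < 0 or self.beta_ear < 0:
            raise InvalidInputError(f"{self.organ_name}: alpha and beta_ear must be >= 0")
        for name in ("alpha_sigma", "R_sigma", "beta_sigma_minus", "beta_sigma_plus"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{self.organ_name}: {name} must be >= 0")
        if self.alpha_beta_ratio <= 0:
            raise InvalidInputError(f"{self.organ_name}: alpha_beta_ratio must be > 0")

    @property
    def beta_sigma(self) -> float:
        """Symmetrised beta uncertainty: the larger of the two printed sigmas."""
        return max(self.beta_sigma_minus, self.beta_sigma_plus)


@dataclass(frozen=True)
class AgeModifierParams:
    """Inputs of the multiplicative age modifier ``mu``.

    ``mu = exp(gamma_exp*(t_exp - 30) + gamma_att*ln(t_att/70))``.  The gamma
    exponents come from the atomic-bomb-survivor analysis and default to 0,
    which pins the model to its reference operating point (exposure at 30,
    attained age 70, mu = 1).
    """

    gamma_exp: float = 0.0
    gamma_att: float = 0.0
    t_exp: float = 30.0
    t_att: float = 70.0

    def __post_init__(self) -> None:
        if self.t_exp <= 0 or self.t_att <= 0:
            raise InvalidInputError("ages must be positive")
        if self.t_att < self.t_exp:
            raise InvalidInputError("attained age must be >= age at exposure")


@dataclass(frozen=True)
class FractionationContext:
    """Fractionation scheme and proton RBE weighting of a plan."""

    n_fractions: int = 15
    rbe_factor: float = 1.1

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise InvalidInputError("n_fractions must be >= 1")
        if self.rbe_factor <= 0:
            raise InvalidInputError("rbe_factor must be > 0")


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def alpha_prime(
    alpha,
    total_voxel_dose,
    ctx: FractionationContext,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
):
    """Effective cell-kill coefficient ``a' = alpha + (alpha/ratio) * d`` [Gy^-1].

    ``d`` is the voxel's dose per fraction, i.e. its *total* dose divided by
    the number of fractions, so low-dose voxels see proportionally low d.
    Broadcasts over arrays of alpha and dose.
    """
    alpha = np.asarray(alpha, dtype=float)
    dose = np.asarray(total_voxel_dose, dtype=float)
    if np.any(alpha < 0):
        raise InvalidInputError("alpha must be >= 0")
    if np.any(dose < 0):
        raise InvalidInputError("dose must be >= 0")
    d = dose / ctx.n_fractions
    out = alpha + (alpha / alpha_beta_ratio) * d
    return out if out.ndim else float(out)


def _red_carcinoma_bracket(ap: np.ndarray, R: np.ndarray, dose: np.ndarray) -> np.ndarray:
    """Generic-R carcinoma RED, in the overflow-free form
    [(1-2R) e^{-a'D} + R^2 - (1-R)^2 e^{-a'D/(1-R)}] / (a'R)."""
    x = ap * dose
    one_minus_R = 1.0 - R
    num = (1.0 - 2.0 * R) * np.exp(-x) + R * R - one_minus_R**2 * np.exp(
        -x / np.where(one_minus_R > 0, one_minus_R, 1.0)
    )
    den = ap * R
    return num / np.where(den > 0, den, 1.0)


def red_carcinoma_values(
    total_voxel_dose,
    alpha,
    repopulation_R,
    ctx: FractionationContext,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
):
    """Carcinoma RED [Gy] for broadcastable arrays of dose, alpha and R.

    Uses analytic limit branches below/above the R switch points, and the
    exact linear-no-threshold limit RED = D where a'D vanishes.
    """
    dose = np.asarray(total_voxel_dose, dtype=float)
    R = np.asarray(repopulation_R, dtype=float)
    if np.any((R < 0) | (R > 1)):
        raise InvalidInputError("repopulation_R must lie in [0, 1]")
    ap = np.asarray(alpha_prime(alpha, dose, ctx, alpha_beta_ratio), dtype=float)
    dose, ap, R = np.broadcast_arrays(dose, ap, R)

    x = ap * dose
    safe_ap = np.where(ap > 0, ap, 1.0)
    low = dose * np.exp(-x)                       # R -> 0 limit
    high = -np.expm1(-x) / safe_ap                # R -> 1 limit
    generic = _red_carcinoma_bracket(np.where(ap > 0, ap, 1.0), np.clip(R, 1e-12, 1 - 1e-12), dose)

    out = np.where(R <= R_LOW_SWITCH, low, np.where(R >= R_HIGH_SWITCH, high, generic))
    out = np.where(x <= 1e-12, dose, out)         # LNT limit, exact at a'D ~ 0
    return out if out.ndim else float(out)


def red_sarcoma_values(
    total_voxel_dose,
    alpha,
    repopulation_R,
    ctx: FractionationContext,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
):
    """Sarcoma RED [Gy]: the carcinoma bracket with the extra -a'RD term,
    equivalently RED_carcinoma - D e^{-a'D}.  Vanishes faster than linearly
    at low dose."""
    dose = np.asarray(total_voxel_dose, dtype=float)
    carc = red_carcinoma_values(dose, alpha, repopulation_R, ctx, alpha_beta_ratio)
    ap = np.asarray(alpha_prime(alpha, dose, ctx, alpha_beta_ratio), dtype=float)
    out = carc - dose * np.exp(-ap * dose)
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def red_carcinoma(total_voxel_dose, params: TissueParams, ctx: FractionationContext):
    """Carcinoma RED [Gy] for a tissue's library parameters."""
    if params.model_kind is not ModelKind.CARCINOMA:
        raise InvalidInputError(f"{params.organ_name} is not a carcinoma tissue")
    return red_carcinoma_values(
        total_voxel_dose, params.alpha, params.repopulation_R, ctx, params.alpha_beta_ratio
    )


def red_sarcoma(total_voxel_dose, params: TissueParams, ctx: FractionationContext):
    """Sarcoma RED [Gy] for a tissue's library parameters."""
    if params.model_kind is not ModelKind.SARCOMA:
        raise InvalidInputError(f"{params.organ_name} is not a sarcoma tissue")
    return red_sarcoma_values(
        total_voxel_dose, params.alpha, params.repopulation_R, ctx, params.alpha_beta_ratio
    )


def red_linear(total_voxel_dose):
    """RED of the linear-no-threshold reference model: the dose itself."""
    dose = np.asarray(total_voxel_dose, dtype=float)
    if np.any(dose < 0):
        raise InvalidInputError("dose must be >= 0")
    return dose if dose.ndim else float(dose)


def age_modifier(p: AgeModifierParams) -> float:
    """Multiplicative age modifier mu(t_exp, t_att).

    Exactly 1 at the reference point (exposure age 30, attained age 70) for
    any gamma exponents.
    """
    return math.exp(p.gamma_exp * (p.t_exp - 30.0) + p.gamma_att * math.log(p.t_att / 70.0))


# ---------------------------------------------------------------------------
# Tissue parameter library
# ---------------------------------------------------------------------------


def _packaged_library_path() -> Path:
    return Path(str(resources.files("voxear").joinpath("data/tissue_params.yaml")))


def load_tissue_library(path: str | Path | None = None) -> dict[str, TissueParams]:
    """Load the per-organ parameter library from YAML.

    Without ``path`` the packaged defaults are used.  Records may override
    the library-wide ``alpha_beta_ratio``; zero-risk organs need no numeric
    fields.
    """
    src = Path(path) if path is not None else _packaged_library_path()
    raw = yaml.safe_load(src.read_text())
    ratio = float(raw.get("alpha_beta_ratio", DEFAULT_ALPHA_BETA_RATIO))
    library: dict[str, TissueParams] = {}
    for organ, rec in raw["organs"].items():
        if rec is None or "model_kind" not in rec:
            raise InvalidInputError(f"malformed record for organ {organ!r}")
        kind = ModelKind(rec["model_kind"])
        library[organ] = TissueParams(
            organ_name=organ,
            model_kind=kind,
            alpha=float(rec.get("alpha", 0.0)),
            alpha_sigma=float(rec.get("alpha_sigma", 0.0)),
            repopulation_R=float(rec.get("repopulation_R", 0.0)),
            R_sigma=float(rec.get("R_sigma", 0.0)),
            beta_ear=float(rec.get("beta_ear", 0.0)),
            beta_sigma_minus=float(rec.get("beta_sigma_minus", 0.0)),
            beta_sigma_plus=float(rec.get("beta_sigma_plus", 0.0)),
            alpha_beta_ratio=float(rec.get("alpha_beta_ratio", ratio)),
        )
    return library


__all__ = [
    "AgeModifierParams",
    "DEFAULT_ALPHA_BETA_RATIO",
    "DEFAULT_ORGAN_ROSTER",
    "EXCLUDED_ORGANS",
    "FractionationContext",
    "InvalidInputError",
    "ModelKind",
    "R_HIGH_SWITCH",
    "R_LOW_SWITCH",
    "TissueParams",
    "age_modifier",
    "alpha_prime",
    "load_tissue_library",
    "red_carcinoma",
    "red_carcinoma_values",
    "red_linear",
    "red_sarcoma",
    "red_sarcoma_values",
]
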