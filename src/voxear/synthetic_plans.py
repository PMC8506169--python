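"""Synthetic phantoms and modality-styled dose fields.

A fixture generator for the whole pipeline: a labelled thorax-like phantom
(the 13-structure roster: lungs, breast, spinal cord, bone, soft-tissue
body, ...) plus analytic dose fields styled after the four modalities the
risk models are meant to compare:

* ``threeD_crt`` — a broad high-dose beam column through the patient with
  sharp lateral Gaussian falloff, moderate bath;
* ``imrt`` / ``vmat`` — dose conformal to the target, paid for by a
  widespread low-dose bath over most of the body;
* ``impt`` — conformal target, minimal bath, and many exact-zero voxels
  (the proton plan's hallmark).

Dose fields are analytic (Gaussian penumbra on a distance transform plus a
sigmoid bath), not beam transport: the artifact exercises the risk
mathematics, not dosimetry.  Everything is deterministic under the spec's
seed.  Default prescription: 30 Gy in 15 fractions to the PTV; the PTV
grows monotonically from stage 1 to stage 5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import expit

from .core_models import FractionationContext, InvalidInputError
from .plan_io import (
    Cuboid,
    Ellipsoid,
    Modality,
    Region,
    VoxelGrid,
    VoxelModel,
    apply_rbe,
    rasterize_structures,
)

#: style name -> treatment modality
STYLE_MODALITY = {
    "threeD_crt": Modality.THREED_CRT,
    "imrt": Modality.IMRT,
    "vmat": Modality.VMAT,
    "impt": Modality.IMPT,
}


@dataclass(frozen=True)
class ModalityStyle:
    """Analytic dose-field styling knobs.

    ``bath_level`` [Gy] and ``bath_extent`` (fraction of body reached by
    the bath) shape the low-dose region; ``penumbra_width`` [cm] is the
    Gaussian falloff scale at the target edge; ``column`` selects the
    broad-beam 3DCRT geometry; doses below ``zero_floor`` [Gy] are set to
    exactly 0 (out-of-field voxels carry exactly zero risk).
    """

    bath_level: float
    bath_extent: float
    penumbra_width: float = 0.5
    column: bool = False
    zero_floor: float = 0.25
    ripple_amp: float = 0.02


DEFAULT_STYLES: dict[str, ModalityStyle] = {
    "threeD_crt": ModalityStyle(bath_level=1.0, bath_extent=0.50, column=True),
    "imrt": ModalityStyle(bath_level=2.5, bath_extent=0.90),
    "vmat": ModalityStyle(bath_level=2.0, bath_extent=0.85),
    "impt": ModalityStyle(bath_level=0.6, bath_extent=0.15, penumbra_width=0.35),
}


@dataclass(frozen=True)
class SyntheticPlanSpec:
    """Parametric description of one phantom + one styled dose field."""

    grid: VoxelGrid
    regions: tuple[Region, ...]
    ptv_region: Region
    prescription: float = 30.0
    n_fractions: int = 15
    modality_style: str = "threeD_crt"
    style: ModalityStyle | None = None  # None -> DEFAULT_STYLES[modality_style]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality_style not in STYLE_MODALITY:
            raise InvalidInputError(f"unknown modality style {self.modality_style!r}")
        if self.prescription <= 0:
            raise InvalidInputError("prescription must be > 0")
        if self.resolved_style.bath_level >= self.prescription:
            raise InvalidInputError("bath level must be below the prescription")

    @property
    def resolved_style(self) -> ModalityStyle:
        return self.style if self.style is not None else DEFAULT_STYLES[self.modality_style]

    @property
    def modality(self) -> Modality:
        return STYLE_MODALITY[self.modality_style]


# ---------------------------------------------------------------------------
# Default phantom geometry (fractions of the grid's physical extent)
# ---------------------------------------------------------------------------

# (name, kind, geometry in fractional coordinates).  x: lateral, y:
# anterior->posterior, z: caudal->cranial.  Small structures nest inside
# larger ones (cord in spine, everything in the soft-tissue body); the
# specificity ordering resolves overlaps.
_PHANTOM_LAYOUT = [
    ("soft_tissue", "cuboid", (0.04, 0.04, 0.04), (0.96, 0.96, 0.96)),
    ("bone", "cuboid", (0.44, 0.60, 0.06), (0.56, 0.80, 0.94)),
    ("spinal_cord", "cuboid", (0.47, 0.65, 0.06), (0.53, 0.75, 0.94)),
    ("lungs", "ellipsoid", (0.29, 0.45, 0.48), (0.15, 0.20, 0.30)),
    ("lungs", "ellipsoid", (0.71, 0.45, 0.48), (0.15, 0.20, 0.30)),
    ("breast", "ellipsoid", (0.32, 0.16, 0.38), (0.13, 0.10, 0.13)),
    ("breast", "ellipsoid", (0.68, 0.16, 0.38), (0.13, 0.10, 0.13)),
    ("heart", "ellipsoid", (0.45, 0.40, 0.28), (0.11, 0.11, 0.11)),
    ("vessels", "cuboid", (0.45, 0.37, 0.40), (0.55, 0.46, 0.58)),
    ("thyroid", "cuboid", (0.44, 0.28, 0.86), (0.56, 0.38, 0.94)),
    ("pharynx", "cuboid", (0.45, 0.40, 0.78), (0.55, 0.50, 0.88)),
    ("oesophagus", "cuboid", (0.46, 0.50, 0.10), (0.54, 0.58, 0.86)),
    ("stomach", "cuboid", (0.28, 0.32, 0.06), (0.48, 0.56, 0.18)),
    ("liver", "cuboid", (0.56, 0.32, 0.06), (0.82, 0.60, 0.22)),
    ("spleen", "cuboid", (0.16, 0.44, 0.06), (0.26, 0.60, 0.16)),
]


def _frac_to_cm(grid: VoxelGrid, f) -> tuple[float, float, float]:
    ext = grid.extent()
    return tuple(ext[i][0] + f[i] * (ext[i][1] - ext[i][0]) for i in range(3))


def _frac_len_to_cm(grid: VoxelGrid, f) -> tuple[float, float, float]:
    ext = grid.extent()
    return tuple(f[i] * (ext[i][1] - ext[i][0]) for i in range(3))


def phantom_regions(grid: VoxelGrid) -> tuple[Region, ...]:
    """The default 13-structure thorax phantom, scaled to the grid."""
    regions: list[Region] = []
    for name, kind, a, b in _PHANTOM_LAYOUT:
        if kind == "cuboid":
            regions.append(Cuboid(name, _frac_to_cm(grid, a), _frac_to_cm(grid, b)))
        else:
            regions.append(Ellipsoid(name, _frac_to_cm(grid, a), _frac_len_to_cm(grid, b)))
    return tuple(regions)


def ptv_region(grid: VoxelGrid, stage: int = 1) -> Cuboid:
    """Mediastinal PTV, growing monotonically from stage 1 to 5."""
    if not 1 <= stage <= 5:
        raise InvalidInputError("stage must be in 1..5")
    hw = 0.10 + 0.022 * stage  # lateral half-width
    z_lo = 0.56 - 0.055 * stage
    z_hi = 0.76 + 0.02 * stage
    lo = (0.5 - hw, 0.30, z_lo)
    hi = (0.5 + hw, 0.55, z_hi)
    return Cuboid("ptv", _frac_to_cm(grid, lo), _frac_to_cm(grid, hi))


def default_spec(
    stage: int = 1,
    modality_style: str = "threeD_crt",
    dims: tuple[int, int, int] = (40, 40, 30),
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4),
    prescription: float = 30.0,
    n_fractions: int = 15,
    seed: int = 0,
) -> SyntheticPlanSpec:
    """A ready-made spec for one disease stage and modality style."""
    grid = VoxelGrid(dims=dims, spacing=spacing)
    return SyntheticPlanSpec(
        grid=grid,
        regions=phantom_regions(grid),
        ptv_region=ptv_region(grid, stage),
        prescription=prescription,
        n_fractions=n_fractions,
        modality_style=modality_style,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Phantom and dose construction
# ---------------------------------------------------------------------------


def build_phantom(spec: SyntheticPlanSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rasterize the spec's regions to a single-valued label field."""
    return rasterize_structures(spec.regions, spec.grid)


def build_dose(spec: SyntheticPlanSpec, labels: np.ndarray) -> np.ndarray:
    """Analytic modality-styled dose field [Gy] on the phantom.

    Target voxels receive the prescription (with a small seeded ripple);
    outside the target the style decides between a broad beam column, a
    conformal Gaussian penumbra, and a sigmoid low-dose bath; dose below
    the style's zero floor is exactly 0, and dose outside the body is 0.
    """
    grid = spec.grid
    style = spec.resolved_style
    body = labels > 0
    ptv = spec.ptv_region.mask(grid)
    if not ptv.any():
        raise InvalidInputError("PTV region contains no voxels")

    # distance [cm] from each voxel to the PTV surface (0 inside)
    dist = distance_transform_edt(~ptv, sampling=grid.spacing)
    high = spec.prescription * np.exp(-0.5 * (dist / style.penumbra_width) ** 2)

    if style.column:
        # broad beam along y: lateral (x, z) distance to the PTV footprint
        ptv_xz = ptv.any(axis=1)
        lat = distance_transform_edt(
            ~ptv_xz, sampling=(grid.spacing[0], grid.spacing[2])
        )
        column = spec.prescription * np.exp(-0.5 * (lat / style.penumbra_width) ** 2)
        high = np.maximum(high, column[:, None, :])

    # low-dose bath reaching ~bath_extent of the body
    body_dist = dist[body]
    r_bath = float(np.quantile(body_dist, min(style.bath_extent, 1.0)))
    bath = style.bath_level * expit((r_bath - dist) / 0.5)

    dose = np.maximum(high, bath)
    if style.ripple_amp > 0:
        rng = np.random.default_rng(spec.seed)
        noise = gaussian_filter(rng.standard_normal(grid.dims), sigma=2.0)
        sd = noise.std()
        if sd > 0:
            dose = dose * (1.0 + style.ripple_amp * noise / sd)
    dose = np.clip(dose, 0.0, None)
    dose[dose < style.zero_floor] = 0.0
    dose[~body] = 0.0
    return dose


def build_plan(spec: SyntheticPlanSpec) -> VoxelModel:
    """Phantom + styled dose as a VoxelModel (physical dose, RBE not applied)."""
    labels, names = build_phantom(spec)
    dose = build_dose(spec, labels)
    return VoxelModel(
        grid=spec.grid,
        labels=labels,
        label_names=names,
        dose=dose,
        modality=spec.modality,
    )


def build_plan_set(
    stage: int = 1,
    styles=("impt", "threeD_crt", "imrt", "vmat"),
    ctx: FractionationContext | None = None,
    dims: tuple[int, int, int] = (40, 40, 30),
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4),
    seed: int = 0,
    **spec_kwargs,
) -> dict[str, VoxelModel]:
    """One RBE-weighted plan per modality style, all sharing the anatomy.

    Keys are modality names ("IMPT", "3DCRT", ...).  The shared label field
    is the precondition for paired plan comparison.
    """
    ctx = ctx or FractionationContext()
    plans: dict[str, VoxelModel] = {}
    for style in styles:
        spec = default_spec(
            stage=stage, modality_style=style, dims=dims, spacing=spacing,
            seed=seed, **spec_kwargs,
        )
        plans[STYLE_MODALITY[style].value] = apply_rbe(build_plan(spec), ctx)
    return plans


def zero_dose_fraction(model: VoxelModel) -> float:
    """Fraction of in-body voxels with exactly zero dose."""
    body = model.labels > 0
    return float((model.dose[body] == 0.0).mean())


def equal_integral_pair(
    stage: int = 1,
    organ: str = "lungs",
    concentrated_fraction: float = 0.25,
    dose: float = 30.0,
    dims: tuple[int, int, int] = (40, 40, 30),
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4),
) -> tuple[VoxelModel, VoxelModel]:
    """Two plans with exactly equal integral dose but different concentration.

    Plan A puts ``dose`` Gy on a contiguous sub-block covering
    ``concentrated_fraction`` of the organ; plan B spreads the same
    dose-volume product uniformly over the whole organ.  Under a nonlinear
    dose-response the two carry different risk despite identical integral
    dose.
    """
    spec = default_spec(stage=stage, dims=dims, spacing=spacing)
    labels, names = build_phantom(spec)
    grid = spec.grid
    mask = labels == names.index(organ)
    n = int(mask.sum())
    if n == 0:
        raise InvalidInputError(f"organ {organ!r} empty on this grid")
    idx = np.argwhere(mask)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    take = idx[order[: max(1, int(round(concentrated_fraction * n)))]]

    dose_a = np.zeros(grid.dims)
    dose_a[tuple(take.T)] = dose
    dose_b = np.zeros(grid.dims)
    dose_b[mask] = dose * len(take) / n

    make = lambda d: VoxelModel(
        grid=grid, labels=labels, label_names=names, dose=d, modality=Modality.OTHER
    )
    return make(dose_a), make(dose_b)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def _region_to_dict(r: Region) -> dict:
    if isinstance(r, Cuboid):
        return {"type": "cuboid", "name": r.name, "lo": list(r.lo), "hi": list(r.hi)}
    return {
        "type": "ellipsoid",
        "name": r.name,
        "center": list(r.center),
        "radii": list(r.radii),
    }


def _region_from_dict(d: dict) -> Region:
    if d["type"] == "cuboid":
        return Cuboid(d["name"], tuple(d["lo"]), tuple(d["hi"]))
    if d["type"] == "ellipsoid":
        return Ellipsoid(d["name"], tuple(d["center"]), tuple(d["radii"]))
    raise InvalidInputError(f"unknown region type {d['type']!r}")


def spec_to_yaml(spec: SyntheticPlanSpec, path: str | Path) -> Path:
    doc = {
        "grid": {
            "dims": list(spec.grid.dims),
            "spacing": list(spec.grid.spacing),
            "origin": list(spec.grid.origin),
        },
        "regions": [_region_to_dict(r) for r in spec.regions],
        "ptv_region": _region_to_dict(spec.ptv_region),
        "prescription": spec.prescription,
        "n_fractions": spec.n_fractions,
        "modality_style": spec.modality_style,
        "style": dataclasses.asdict(spec.style) if spec.style is not None else None,
        "seed": spec.seed,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def spec_from_yaml(path: str | Path) -> SyntheticPlanSpec:
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["grid"]
    return SyntheticPlanSpec(
        grid=VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"])),
        regions=tuple(_region_from_dict(d) for d in doc["regions"]),
        ptv_region=_region_from_dict(doc["ptv_region"]),
        prescription=doc["prescription"],
        n_fractions=doc["n_fractions"],
        modality_style=doc["modality_style"],
        style=ModalityStyle(**doc["style"]) if doc.get("style") else None,
        seed=doc["seed"],
    )


__all__ = [
    "DEFAULT_STYLES",
    "ModalityStyle",
    "STYLE_MODALITY",
    "SyntheticPlanSpec",
    "build_dose",
    "build_phantom",
    "build_plan",
    "build_plan_set",
    "default_spec",
    "equal_integral_pair",
    "phantom_regions",
    "ptv_region",
    "spec_from_yaml",
    "spec_to_yaml",
    "zero_dose_fraction",
]
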