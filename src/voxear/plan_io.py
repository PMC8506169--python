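"""Co-registered voxel models: labels, dose, and DICOM-RT ingestion.

Conventions (used everywhere in the package): voxel-centre sampling,
0-based indices, axis order (x, y, z), spacing and coordinates in cm.
DICOM patient coordinates (mm, array order z/y/x) are converted at the
import/export boundary.

Every in-patient voxel carries exactly one structure label.  Where contours
overlap, the most specific structure wins, according to an explicit
specificity ordering (earlier in the list = more specific); voxels inside
no contour are "unlabelled" and excluded from risk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core_models import FractionationContext, InvalidInputError

logger = logging.getLogger("voxear")

UNLABELLED = "unlabelled"

#: default CT-resolution spacing, cm
DEFAULT_SPACING = (0.1055, 0.1055, 0.2500)

#: default specificity ordering, most specific first.  Small structures
#: survive inside the larger ones that enclose them (cord inside bone,
#: everything inside the soft-tissue body).
DEFAULT_SPECIFICITY_ORDER = (
    "spinal_cord",
    "thyroid",
    "pharynx",
    "oesophagus",
    "vessels",
    "heart",
    "stomach",
    "liver",
    "spleen",
    "breast",
    "lungs",
    "bone",
    "soft_tissue",
)


class Modality(str, Enum):
    IMPT = "IMPT"
    THREED_CRT = "3DCRT"
    IMRT = "IMRT"
    VMAT = "VMAT"
    OTHER = "other"

    @property
    def is_proton(self) -> bool:
        return self is Modality.IMPT


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: dims (nx, ny, nz), spacing and origin in cm.

    ``origin`` is the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(n < 1 for n in self.dims):
            raise InvalidInputError("dims must be 3 positive integers")
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError("spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, cm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, cm."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical (min, max) voxel-centre coordinates per axis, cm."""
        return tuple(
            (self.origin[i], self.origin[i] + self.spacing[i] * (self.dims[i] - 1))
            for i in range(3)
        )


# ---------------------------------------------------------------------------
# Structure regions and rasterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned box region; lo/hi are physical corner coordinates in cm."""

    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        axes = [grid.axis_coords(i) for i in range(3)]
        m1 = (axes[0] >= self.lo[0]) & (axes[0] <= self.hi[0])
        m2 = (axes[1] >= self.lo[1]) & (axes[1] <= self.hi[1])
        m3 = (axes[2] >= self.lo[2]) & (axes[2] <= self.hi[2])
        return m1[:, None, None] & m2[None, :, None] & m3[None, None, :]

    def bounds(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        return self.lo, self.hi


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid region; centre and semi-axes in cm."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        axes = [grid.axis_coords(i) for i in range(3)]
        u = (axes[0] - self.center[0]) / self.radii[0]
        v = (axes[1] - self.center[1]) / self.radii[1]
        w = (axes[2] - self.center[2]) / self.radii[2]
        return (
            u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2
        ) <= 1.0

    def bounds(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        lo = tuple(c - r for c, r in zip(self.center, self.radii))
        hi = tuple(c + r for c, r in zip(self.center, self.radii))
        return lo, hi  # type: ignore[return-value]


Region = Cuboid | Ellipsoid


def rasterize_structures(
    regions,
    grid: VoxelGrid,
    specificity_order=DEFAULT_SPECIFICITY_ORDER,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rasterize named regions to a single-valued label field.

    Returns ``(labels, label_names)`` where ``labels`` is an int16 array of
    indices into ``label_names`` and ``label_names[0]`` is "unlabelled".
    Regions are painted from least to most specific, so where contours
    overlap the most specific structure is retained.  Regions extending
    beyond the grid are clipped with a warning.
    """
    names = [UNLABELLED]
    for r in regions:
        if r.name not in names:
            names.append(r.name)
    order = {name: i for i, name in enumerate(specificity_order)}
    for r in regions:
        if r.name not in order:
            raise InvalidInputError(
                f"structure {r.name!r} missing from the specificity ordering"
            )
    # physical grid coverage: half a voxel beyond the outermost centres
    ext = [
        (lo - grid.spacing[i] / 2, hi + grid.spacing[i] / 2)
        for i, (lo, hi) in enumerate(grid.extent())
    ]
    labels = np.zeros(grid.dims, dtype=np.int16)
    # least specific first so later (more specific) paints win
    for r in sorted(regions, key=lambda r: order[r.name], reverse=True):
        lo, hi = r.bounds()
        if any(lo[i] < ext[i][0] or hi[i] > ext[i][1] for i in range(3)):
            warnings.warn(f"structure {r.name!r} extends beyond the grid; clipped")
        labels[r.mask(grid)] = names.index(r.name)
    return labels, tuple(names)


# ---------------------------------------------------------------------------
# Voxel model
# ---------------------------------------------------------------------------


@dataclass
class VoxelModel:
    """Co-registered label and dose fields on one grid.

    ``labels`` indexes ``label_names`` (index 0 = unlabelled); ``dose`` is
    absorbed dose in Gy, RBE-weighted once :func:`apply_rbe` has run (the
    ``rbe_applied`` flag guards against double weighting).
    """

    grid: VoxelGrid
    labels: np.ndarray
    label_names: tuple[str, ...]
    dose: np.ndarray
    modality: Modality = Modality.OTHER
    rbe_applied: bool = False

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.labels.shape != tuple(self.grid.dims) or self.dose.shape != tuple(self.grid.dims):
            raise InvalidInputError("labels/dose shapes must match the grid dims")
        if np.any(self.dose < 0):
            raise InvalidInputError("dose must be >= 0 everywhere")
        if self.label_names[0] != UNLABELLED:
            raise InvalidInputError("label_names[0] must be 'unlabelled'")

    def organ_mask(self, organ: str) -> np.ndarray:
        if organ not in self.label_names:
            raise KeyError(f"organ {organ!r} not present in this model")
        return self.labels == self.label_names.index(organ)

    def organ_voxel_count(self, organ: str) -> int:
        return int(self.organ_mask(organ).sum()) if organ in self.label_names else 0

    @property
    def present_organs(self) -> tuple[str, ...]:
        present = np.bincount(self.labels.ravel(), minlength=len(self.label_names)) > 0
        return tuple(
            n for i, n in enumerate(self.label_names) if i > 0 and present[i]
        )


def resample_dose(
    source_dose: np.ndarray,
    source_grid: VoxelGrid,
    target: VoxelGrid,
) -> np.ndarray:
    """Trilinearly interpolate a dose field onto a target grid.

    Voxel centres outside the source support are filled with 0 Gy; the
    count of such voxels is logged.  Interpolation is convex, so the result
    is bounded by the source dose range.
    """
    if any(n < 2 for n in source_grid.dims):
        raise InvalidInputError("source grid must have >= 2 samples per axis")
    axes = [source_grid.axis_coords(i) for i in range(3)]
    interp = RegularGridInterpolator(
        axes, source_dose, method="linear", bounds_error=False, fill_value=0.0
    )
    tx, ty, tz = (target.axis_coords(i) for i in range(3))
    pts = np.stack(np.meshgrid(tx, ty, tz, indexing="ij"), axis=-1)
    out = interp(pts.reshape(-1, 3)).reshape(target.dims)
    ext = source_grid.extent()
    inside = np.ones(target.dims, dtype=bool)
    for i, coords in enumerate((tx, ty, tz)):
        ax_in = (coords >= ext[i][0]) & (coords <= ext[i][1])
        inside &= ax_in.reshape([-1 if j == i else 1 for j in range(3)])
    n_out = int((~inside).sum())
    if n_out:
        logger.info("resample_dose: %d target voxels outside source support set to 0 Gy", n_out)
    return np.maximum(out, 0.0)


def apply_rbe(model: VoxelModel, ctx: FractionationContext) -> VoxelModel:
    """Return a copy with proton dose multiplied by the RBE factor.

    Photon plans pass through unchanged.  Weighting twice is an error.
    """
    if model.rbe_applied:
        raise InvalidInputError("RBE weighting already applied to this model")
    dose = model.dose * ctx.rbe_factor if model.modality.is_proton else model.dose.copy()
    return dataclasses.replace(model, dose=dose, rbe_applied=True)


# ---------------------------------------------------------------------------
# Serialization (.npz arrays + JSON sidecar)
# ---------------------------------------------------------------------------


def save_voxel_model(model: VoxelModel, path: str | Path) -> Path:
    """Write labels/dose as compressed arrays plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), labels=model.labels, dose=model.dose)
    sidecar = {
        "dims": list(model.grid.dims),
        "spacing": list(model.grid.spacing),
        "origin": list(model.grid.origin),
        "label_names": list(model.label_names),
        "modality": model.modality.value,
        "rbe_applied": model.rbe_applied,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_voxel_model(path: str | Path) -> VoxelModel:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    grid = VoxelGrid(tuple(side["dims"]), tuple(side["spacing"]), tuple(side["origin"]))
    return VoxelModel(
        grid=grid,
        labels=arrays["labels"],
        label_names=tuple(side["label_names"]),
        dose=arrays["dose"],
        modality=Modality(side["modality"]),
        rbe_applied=side["rbe_applied"],
    )


# ---------------------------------------------------------------------------
# DICOM-RT import / export (pydicom); mm <-> cm at this boundary
# ---------------------------------------------------------------------------


def _dicom_dataset(sop_class: str, modality: str, frame_uid: str):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "synthetic^phantom"
    ds.PatientID = "SYN000"
    ds.FrameOfReferenceUID = frame_uid
    return ds


def export_dicom_rt(
    model: VoxelModel,
    regions,
    out_dir: str | Path,
    n_contour_points: int = 64,
) -> dict[str, Path]:
    """Write a minimal DICOM-RT triplet (CT series, RTSTRUCT, RTDOSE).

    Intended for round-trip testing of synthetic plans: contours are
    generated analytically from the plan's regions (rectangles for cuboids,
    sampled ellipses for ellipsoids), one closed planar contour per CT
    slice the region intersects.
    """
    import pydicom
    from pydicom.dataset import Dataset
    from pydicom.uid import generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = model.grid
    frame_uid = generate_uid()
    nx, ny, nz = grid.dims
    # mm quantities for DICOM
    sp_mm = [s * 10.0 for s in grid.spacing]
    org_mm = [o * 10.0 for o in grid.origin]
    z_mm = [org_mm[2] + sp_mm[2] * k for k in range(nz)]

    ct_class = "1.2.840.10008.5.1.4.1.1.2"
    ct_dir = out_dir / "ct"
    ct_dir.mkdir(exist_ok=True)
    series_uid = generate_uid()
    ct_paths = []
    for k in range(nz):
        ds = _dicom_dataset(ct_class, "CT", frame_uid)
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [org_mm[0], org_mm[1], z_mm[k]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sp_mm[1], sp_mm[0]]  # row (y), column (x)
        ds.SliceThickness = sp_mm[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        ds.PixelData = np.zeros((ny, nx), dtype=np.uint16).tobytes()
        p = ct_dir / f"ct_{k:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        ct_paths.append(p)

    # RTSTRUCT: one planar contour per slice intersected by each region
    rs = _dicom_dataset("1.2.840.10008.5.1.4.1.1.481.3", "RTSTRUCT", frame_uid)
    rs.StructureSetLabel = "synthetic"
    roi_seq, con_seq = [], []
    for number, region in enumerate(regions, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = region.name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi_seq.append(roi)
        contours = []
        lo, hi = region.bounds()
        for k, z in enumerate(z_mm):
            zcm = z / 10.0
            if not (lo[2] <= zcm <= hi[2]):
                continue
            if isinstance(region, Cuboid):
                xy = [
                    (region.lo[0], region.lo[1]),
                    (region.hi[0], region.lo[1]),
                    (region.hi[0], region.hi[1]),
                    (region.lo[0], region.hi[1]),
                ]
            else:  # ellipsoid: in-plane ellipse at this z
                frac = 1.0 - ((zcm - region.center[2]) / region.radii[2]) ** 2
                if frac <= 0:
                    continue
                a = region.radii[0] * np.sqrt(frac)
                b = region.radii[1] * np.sqrt(frac)
                t = np.linspace(0, 2 * np.pi, n_contour_points, endpoint=False)
                xy = list(
                    zip(region.center[0] + a * np.cos(t), region.center[1] + b * np.sin(t))
                )
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(xy)
            c.ContourData = [
                float(v) for x, y in xy for v in (x * 10.0, y * 10.0, z)
            ]
            contours.append(c)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = contours
        con_seq.append(rc)
    rs.StructureSetROISequence = roi_seq
    rs.ROIContourSequence = con_seq
    rs_path = out_dir / "rtstruct.dcm"
    rs.save_as(rs_path, enforce_file_format=True)

    # RTDOSE: pixel data (z, y, x) as uint32 with a DoseGridScaling factor
    rd = _dicom_dataset("1.2.840.10008.5.1.4.1.1.481.2", "RTDOSE", frame_uid)
    rd.DoseUnits = "GY"
    rd.DoseType = "PHYSICAL"
    rd.DoseSummationType = "PLAN"
    rd.ImagePositionPatient = [org_mm[0], org_mm[1], z_mm[0]]
    rd.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    rd.PixelSpacing = [sp_mm[1], sp_mm[0]]
    rd.GridFrameOffsetVector = [sp_mm[2] * k for k in range(nz)]
    rd.NumberOfFrames = nz
    rd.Rows, rd.Columns = ny, nx
    rd.BitsAllocated = rd.BitsStored = 32
    rd.HighBit = 31
    rd.PixelRepresentation = 0
    rd.SamplesPerPixel = 1
    rd.PhotometricInterpretation = "MONOCHROME2"
    max_dose = float(model.dose.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    stored = np.round(model.dose / scaling).astype(np.uint32) if max_dose > 0 else np.zeros(
        grid.dims, dtype=np.uint32
    )
    rd.DoseGridScaling = scaling
    rd.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    rd_path = out_dir / "rtdose.dcm"
    rd.save_as(rd_path, enforce_file_format=True)

    return {"ct": ct_dir, "rtstruct": rs_path, "rtdose": rd_path}


def _grid_from_ct(ct_dir: Path) -> VoxelGrid:
    import pydicom

    slices = sorted(
        (pydicom.dcmread(p) for p in sorted(Path(ct_dir).glob("*.dcm"))),
        key=lambda s: float(s.ImagePositionPatient[2]),
    )
    if not slices:
        raise InvalidInputError(f"no CT slices found in {ct_dir}")
    first = slices[0]
    dz = (
        float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
        if len(slices) > 1
        else float(getattr(first, "SliceThickness", 1.0))
    )
    return VoxelGrid(
        dims=(int(first.Columns), int(first.Rows), len(slices)),
        spacing=(
            float(first.PixelSpacing[1]) / 10.0,
            float(first.PixelSpacing[0]) / 10.0,
            dz / 10.0,
        ),
        origin=tuple(float(v) / 10.0 for v in first.ImagePositionPatient),
    )


def import_dicom_rt(
    ct_path: str | Path | None,
    rtstruct_path: str | Path,
    rtdose_path: str | Path,
    alias_map: dict[str, str] | None = None,
    specificity_order=DEFAULT_SPECIFICITY_ORDER,
    unmapped: str = "warn",
    modality: Modality | str = Modality.OTHER,
) -> VoxelModel:
    """Build a VoxelModel from a DICOM-RT triplet.

    The CT series defines the grid (falling back to the RTDOSE grid when
    ``ct_path`` is None).  RTSTRUCT contours are rasterized slice-wise onto
    that grid, structure names mapped through ``alias_map`` to library
    names; RTDOSE is scaled by DoseGridScaling and trilinearly resampled.
    ``unmapped`` controls unknown structure names: "warn" treats them as
    soft tissue, "exclude" drops them, "error" raises.
    """
    import pydicom
    from skimage.draw import polygon as sk_polygon

    rs = pydicom.dcmread(rtstruct_path)
    rd = pydicom.dcmread(rtdose_path)
    if str(rs.FrameOfReferenceUID) != str(rd.FrameOfReferenceUID):
        raise InvalidInputError("RTSTRUCT and RTDOSE frame-of-reference mismatch")

    dose_grid = VoxelGrid(
        dims=(int(rd.Columns), int(rd.Rows), int(rd.NumberOfFrames)),
        spacing=(
            float(rd.PixelSpacing[1]) / 10.0,
            float(rd.PixelSpacing[0]) / 10.0,
            (
                float(rd.GridFrameOffsetVector[1]) - float(rd.GridFrameOffsetVector[0])
            )
            / 10.0
            if int(rd.NumberOfFrames) > 1
            else 0.1,
        ),
        origin=tuple(float(v) / 10.0 for v in rd.ImagePositionPatient),
    )
    grid = _grid_from_ct(Path(ct_path)) if ct_path is not None else dose_grid

    alias_map = alias_map or {}
    names = {int(r.ROINumber): str(r.ROIName) for r in rs.StructureSetROISequence}
    order = {name: i for i, name in enumerate(specificity_order)}

    structures: list[tuple[str, list]] = []
    for rc in rs.ROIContourSequence:
        raw_name = names[int(rc.ReferencedROINumber)]
        name = alias_map.get(raw_name, alias_map.get(raw_name.lower(), raw_name))
        if name not in order:
            if unmapped == "error":
                raise InvalidInputError(f"unmapped structure {raw_name!r}")
            warnings.warn(f"structure {raw_name!r} not in the tissue mapping")
            if unmapped == "exclude":
                continue
            name = "soft_tissue"
        structures.append((name, list(getattr(rc, "ContourSequence", []))))

    labels = np.zeros(grid.dims, dtype=np.int16)
    label_names = [UNLABELLED] + sorted({n for n, _ in structures}, key=lambda n: order[n])
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.spacing
    # least specific painted first
    for name, contours in sorted(structures, key=lambda t: order[t[0]], reverse=True):
        code = label_names.index(name)
        for c in contours:
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3) / 10.0  # cm
            k = int(round((pts[0, 2] - oz) / sz))
            if not 0 <= k < grid.dims[2]:
                continue
            cols = (pts[:, 0] - ox) / sx  # x index
            rows = (pts[:, 1] - oy) / sy  # y index
            rr, cc = sk_polygon(rows, cols, shape=(grid.dims[1], grid.dims[0]))
            labels[cc, rr, k] = code

    stored = rd.pixel_array.astype(float) * float(rd.DoseGridScaling)  # (z, y, x)
    dose_src = np.ascontiguousarray(stored.transpose(2, 1, 0))  # (x, y, z)
    dose = (
        dose_src
        if grid == dose_grid
        else resample_dose(dose_src, dose_grid, grid)
    )
    return VoxelModel(
        grid=grid,
        labels=labels,
        label_names=tuple(label_names),
        dose=dose,
        modality=Modality(modality),
    )


def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Structure-name alias table (clinical names -> library names)."""
    import yaml
    from importlib import resources

    src = (
        Path(path)
        if path is not None
        else Path(str(resources.files("voxear").joinpath("data/structure_aliases.yaml")))
    )
    return dict(yaml.safe_load(src.read_text()))


__all__ = [
    "Cuboid",
    "DEFAULT_SPACING",
    "DEFAULT_SPECIFICITY_ORDER",
    "Ellipsoid",
    "Modality",
    "Region",
    "UNLABELLED",
    "VoxelGrid",
    "VoxelModel",
    "apply_rbe",
    "export_dicom_rt",
    "import_dicom_rt",
    "load_alias_map",
    "load_voxel_model",
    "rasterize_structures",
    "resample_dose",
    "save_voxel_model",
]
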