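"""NIfTI volume I/O, grid resampling and cohort manifest handling.

Volumes are stored as NIfTI-1 with a diagonal affine (axis-aligned grids
only); vector fields as 4D NIfTI with the three displacement components on
the last axis. The cohort manifest is a CSV with columns patient_id,
outcome, image_path, dose_path, mask_dir; the first row is the
common-coordinate-system reference patient.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import DeformationField, VelocityField
from .grids import BinaryMask, Grid, ScalarVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "resample_to_grid",
    "resample_mask_to_grid",
    "write_cohort",
    "read_manifest",
    "CohortManifest",
]

MANIFEST_COLUMNS = ["patient_id", "outcome", "image_path", "dose_path", "mask_dir"]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(affine: np.ndarray, shape) -> Grid:
    rot = affine[:3, :3]
    diag = np.diag(rot)
    if not np.allclose(rot, np.diag(diag), atol=1e-6):
        raise ValueError(
            "oblique/rotated NIfTI grids are not supported (axis-aligned only)"
        )
    if np.any(diag <= 0):
        raise ValueError("negative or zero affine scales are not supported")
    return Grid(tuple(int(s) for s in shape[:3]), tuple(float(d) for d in diag),
                tuple(float(o) for o in affine[:3, 3]))


def write_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.grid))
    nib.save(img, str(path))


def read_volume(path) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D scalar volume")
    return ScalarVolume(data, _grid_from_affine(img.affine, data.shape))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def read_mask(path, name: str = "") -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D mask volume")
    return BinaryMask(data > 0.5, _grid_from_affine(img.affine, data.shape),
                      name or path.stem.replace(".nii", ""))


def write_field(field: VelocityField | DeformationField, path) -> None:
    img = nib.Nifti1Image(field.data.astype(np.float64), _affine(field.grid))
    nib.save(img, str(path))


def read_field(path, kind: str = "velocity") -> VelocityField | DeformationField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{path} is not a 3-component vector field")
    grid = _grid_from_affine(img.affine, data.shape)
    cls = VelocityField if kind == "velocity" else DeformationField
    return cls(data, grid)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _world_to_source_coords(target: Grid, source: Grid) -> np.ndarray:
    coords = np.indices(target.shape, dtype=np.float64)
    for a in range(3):
        world = target.origin[a] + coords[a] * target.spacing[a]
        coords[a] = (world - source.origin[a]) / source.spacing[a]
    return coords


def _check_overlap(target: Grid, source: Grid) -> None:
    for a in range(3):
        t_lo, t_hi = target.origin[a], target.origin[a] + (target.shape[a] - 1) * target.spacing[a]
        s_lo, s_hi = source.origin[a], source.origin[a] + (source.shape[a] - 1) * source.spacing[a]
        if t_hi < s_lo or s_hi < t_lo:
            raise ValueError(f"grids have disjoint physical extents along axis {a}")


def resample_to_grid(
    vol: ScalarVolume, target: Grid, mode: str = "trilinear", fill: float = 0.0
) -> ScalarVolume:
    """Resample a scalar volume onto a target grid in world coordinates."""
    if vol.grid.same_as(target):
        return vol.copy()
    _check_overlap(target, vol.grid)
    order = {"trilinear": 1, "nearest": 0}[mode]
    coords = _world_to_source_coords(target, vol.grid)
    data = ndimage.map_coordinates(vol.data, coords, order=order, mode="constant",
                                   cval=float(fill))
    return ScalarVolume(data, target)


def resample_mask_to_grid(mask: BinaryMask, target: Grid) -> BinaryMask:
    if mask.grid.same_as(target):
        return mask.copy()
    _check_overlap(target, mask.grid)
    coords = _world_to_source_coords(target, mask.grid)
    data = ndimage.map_coordinates(mask.data.astype(np.float64), coords, order=0,
                                   mode="constant", cval=0.0)
    return BinaryMask(data > 0.5, target, mask.name)


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------

class CohortManifest:
    """Validated view of a cohort manifest CSV.

    The first row is the reference patient whose anatomy defines the common
    coordinate system.
    """

    def __init__(self, df: pd.DataFrame, root: Path):
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if df["patient_id"].duplicated().any():
            raise ValueError("manifest patient ids must be unique")
        if not set(df["outcome"].unique()) <= {0, 1}:
            raise ValueError("manifest outcomes must be 0/1")
        self.df = df.reset_index(drop=True)
        self.root = Path(root)
        for _, row in self.df.iterrows():
            for key in ("image_path", "dose_path", "mask_dir"):
                p = self._resolve(row[key])
                if not p.exists():
                    raise FileNotFoundError(f"{key} for {row['patient_id']}: {p}")

    def _resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.root / p

    @property
    def reference_id(self) -> str:
        return str(self.df.iloc[0]["patient_id"])

    def __len__(self) -> int:
        return len(self.df)

    def patient(self, i: int) -> dict:
        row = self.df.iloc[i]
        mask_dir = self._resolve(row["mask_dir"])
        masks = sorted(mask_dir.glob("*.nii.gz"))
        return {
            "patient_id": str(row["patient_id"]),
            "outcome": int(row["outcome"]),
            "image": self._resolve(row["image_path"]),
            "dose": self._resolve(row["dose_path"]),
            "masks": masks,
        }


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return CohortManifest(pd.read_csv(path), path.parent)


def write_cohort(dataset, outdir) -> Path:
    """Write a generated cohort as per-patient NIfTI files plus manifest CSV.

    Layout: <outdir>/<pid>/image.nii.gz, dose.nii.gz, masks/<name>.nii.gz and
    <outdir>/manifest.csv (reference patient first).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        pdir = outdir / rec.id
        (pdir / "masks").mkdir(parents=True, exist_ok=True)
        write_volume(rec.image, pdir / "image.nii.gz")
        if rec.dose is not None:
            write_volume(rec.dose, pdir / "dose.nii.gz")
        for name, mask in rec.structures.items():
            write_mask(mask, pdir / "masks" / f"{name}.nii.gz")
        write_field(rec.true_velocity, pdir / "true_velocity.nii.gz")
        rows.append({
            "patient_id": rec.id,
            "outcome": rec.outcome,
            "image_path": f"{rec.id}/image.nii.gz",
            "dose_path": f"{rec.id}/dose.nii.gz",
            "mask_dir": f"{rec.id}/masks",
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    # ground-truth CCS annotations for validation studies
    write_mask(dataset.sensitive_in_ccs(), outdir / "ccs_sensitive_region.nii.gz")
    write_mask(dataset.roi_in_ccs(), outdir / "ccs_swallowing_roi.nii.gz")
    return manifest


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
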