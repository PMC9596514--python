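"""Volume, label-map and point-set I/O.

Conventions used throughout the package:

* A volume is a 3D array indexed ``data[i, j, k]``; axis 2 (``k``) is the
  anatomical z axis along which the tooth is aligned (apical = +z after
  alignment).
* Voxel indices are 0-based.  The physical coordinate (µm) of a voxel
  center is ``origin_um + index * voxel_size_um``.
* Only isotropic volumes are accepted; anisotropic spacing in a file
  header is a hard error, never a silent resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "Seed",
    "SeedSet",
    "CEJPointSet",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_seeds",
    "write_seeds",
    "read_cej_points",
    "write_cej_points",
]

_ISO_RTOL = 1e-3  # relative tolerance when checking header spacing isotropy


def _check_3d(data: np.ndarray, what: str) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValueError(f"{what} must be a 3D array with each axis >= 1, got shape {data.shape}")


@dataclass
class Volume:
    """A 3D scalar image with isotropic voxel size in µm."""

    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data, "Volume.data")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if self.origin_um.shape != (3,):
            raise ValueError("origin_um must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer tissue labels on a voxel grid.

    ``palette`` maps label id -> tissue name (``air``, ``bone``,
    ``tooth`` or ``tooth_<quadrant>``).  After watershed segmentation the
    labels form a partition: every voxel carries exactly one positive id.
    """

    labels: np.ndarray
    palette: dict[int, str]
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_3d(self.labels, "LabelMap.labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap.labels must have an integer dtype")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.palette = {int(k): str(v) for k, v in self.palette.items()}
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.palette)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} present in grid but absent from palette")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def id_of(self, name: str) -> int:
        """Label id for a tissue name; tooth labels match any ``tooth*`` name."""
        for lid, lname in self.palette.items():
            if lname == name:
                return lid
        raise KeyError(f"no label named {name!r} in palette {self.palette}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.id_of(name)

    def tooth_ids(self) -> list[int]:
        return [lid for lid, lname in self.palette.items() if lname.startswith("tooth")]


@dataclass(frozen=True)
class Seed:
    label: str
    ijk: tuple[int, int, int]


@dataclass
class SeedSet:
    """Manually (or synthetically) placed tissue seed voxels."""

    seeds: list[Seed]

    def __post_init__(self) -> None:
        self.seeds = [Seed(s.label, tuple(int(x) for x in s.ijk)) for s in self.seeds]

    def __len__(self) -> int:
        return len(self.seeds)

    def labels(self) -> list[str]:
        """Distinct label names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.seeds:
            seen.setdefault(s.label, None)
        return list(seen)

    def validate_bounds(self, shape: Sequence[int]) -> None:
        for s in self.seeds:
            if any(c < 0 or c >= n for c, n in zip(s.ijk, shape)):
                raise ValueError(f"seed {s.ijk} ({s.label}) outside volume of shape {tuple(shape)}")

    def mirrored(self, shape: Sequence[int], axis: int = 0) -> "SeedSet":
        out = []
        for s in self.seeds:
            ijk = list(s.ijk)
            ijk[axis] = shape[axis] - 1 - ijk[axis]
            out.append(Seed(s.label, tuple(ijk)))
        return SeedSet(out)


@dataclass
class CEJPointSet:
    """>= 3 non-collinear points on the cementoenamel junction, in µm."""

    points_um: np.ndarray

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 3:
            raise ValueError("CEJ points must be an (n, 3) array")
        if self.points_um.shape[0] < 3:
            raise ValueError(f"need >= 3 CEJ points, got {self.points_um.shape[0]}")
        centered = self.points_um - self.points_um.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("CEJ points are collinear; plane is undefined")

    def __len__(self) -> int:
        return self.points_um.shape[0]


# ---------------------------------------------------------------------------
# volume readers / writers


def _require_isotropic(zooms: Sequence[float], source: str) -> float:
    zooms = np.asarray(zooms, dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=_ISO_RTOL):
        raise ValueError(
            f"{source} has anisotropic spacing {tuple(zooms)}; only isotropic volumes are supported"
        )
    return float(zooms[0])


def read_volume(path: str | Path, format: str | None = None, voxel_size_um: float | None = None) -> Volume:
    """Read a 3D volume from a TIFF stack, NIfTI-1 or MetaImage file.

    ``format`` is one of ``tiff_stack``, ``nifti``, ``mhd``; if omitted it
    is inferred from the file suffix.  TIFF carries no spacing, so
    ``voxel_size_um`` is required for it; for NIfTI/MHD the header spacing
    is used (interpreted in µm) and must be isotropic.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        import tifffile

        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF stacks (TIFF stores no spacing)")
        arr = tifffile.imread(str(path))
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got shape {arr.shape}")
        # pages are z slices -> (z, y, x); reorder to (x, y, z)
        return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)), voxel_size_um)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = _require_isotropic(img.header.get_zooms()[:3], path.name)
        if voxel_size_um is not None and not np.isclose(spacing, voxel_size_um, rtol=_ISO_RTOL):
            raise ValueError(
                f"header spacing {spacing} conflicts with requested voxel size {voxel_size_um}"
            )
        data = np.asanyarray(img.dataobj)
        return Volume(np.ascontiguousarray(data), spacing)
    if fmt == "mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = _require_isotropic(img.GetSpacing(), path.name)
        if voxel_size_um is not None and not np.isclose(spacing, voxel_size_um, rtol=_ISO_RTOL):
            raise ValueError(
                f"header spacing {spacing} conflicts with requested voxel size {voxel_size_um}"
            )
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)), spacing)
    raise ValueError(f"unknown volume format {fmt!r}")


def write_volume(volume: Volume, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff_stack":
        import tifffile

        tifffile.imwrite(str(path), np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([volume.voxel_size_um] * 3 + [1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(volume.data), affine)
        img.header.set_zooms((volume.voxel_size_um,) * 3)
        nib.save(img, str(path))
    elif fmt == "mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing((volume.voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mhd", ".mha")):
        return "mhd"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def _palette_sidecar(path: Path) -> Path:
    return path.parent / (path.name.split(".")[0] + ".palette.json")


def write_labelmap(labelmap: LabelMap, path: str | Path, format: str | None = None) -> Path:
    """Write integer labels plus a JSON palette sidecar (lossless round trip)."""
    path = Path(path)
    vol = Volume(labelmap.labels.astype(np.int32), labelmap.voxel_size_um, labelmap.origin_um)
    write_volume(vol, path, format)
    sidecar = _palette_sidecar(path)
    sidecar.write_text(
        json.dumps(
            {
                "palette": {str(k): v for k, v in labelmap.palette.items()},
                "voxel_size_um": labelmap.voxel_size_um,
                "origin_um": labelmap.origin_um.tolist(),
            },
            indent=2,
        )
    )
    return path


def read_labelmap(path: str | Path, format: str | None = None) -> LabelMap:
    path = Path(path)
    sidecar = _palette_sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"palette sidecar {sidecar} not found")
    side = json.loads(sidecar.read_text())
    vol = read_volume(path, format, voxel_size_um=side.get("voxel_size_um"))
    return LabelMap(
        vol.data.astype(np.int32),
        {int(k): v for k, v in side["palette"].items()},
        float(side["voxel_size_um"]),
        np.asarray(side.get("origin_um", [0.0, 0.0, 0.0])),
    )


# ---------------------------------------------------------------------------
# point files


def read_seeds(path: str | Path, shape: Sequence[int] | None = None) -> SeedSet:
    """Read seeds from JSON: ``[{"label": "bone", "ijk": [i, j, k]}, ...]``."""
    entries = json.loads(Path(path).read_text())
    seeds = SeedSet([Seed(e["label"], tuple(e["ijk"])) for e in entries])
    if shape is not None:
        seeds.validate_bounds(shape)
    else:
        for s in seeds.seeds:
            if any(c < 0 for c in s.ijk):
                raise ValueError(f"seed {s.ijk} has a negative index")
    return seeds


def write_seeds(seeds: SeedSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([{"label": s.label, "ijk": list(s.ijk)} for s in seeds.seeds], indent=2))
    return path


def read_cej_points(path: str | Path) -> CEJPointSet:
    """Read CEJ points from JSON: ``{"points_um": [[x, y, z], ...]}``."""
    obj = json.loads(Path(path).read_text())
    pts = obj["points_um"] if isinstance(obj, Mapping) else obj
    return CEJPointSet(np.asarray(pts, dtype=float))


def write_cej_points(points: CEJPointSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"points_um": points.points_um.tolist()}, indent=2))
    return path
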