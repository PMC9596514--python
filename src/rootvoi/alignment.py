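"""Rigid alignment of the segmented quadrant to the CEJ reference frame.

A plane is fitted through the manually picked cementoenamel-junction
(CEJ) points by principal component analysis; the minimal rotation taking
the plane normal onto the z axis is applied to the label map (about the
CEJ centroid), so that after alignment the CEJ plane is z = 0 and the
root (apical) direction is +z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .volume_io import CEJPointSet, LabelMap

__all__ = [
    "RigidTransform",
    "fit_cej_plane",
    "orient_normal_apical",
    "transform_to_z",
    "apply_transform",
]

_ORTHO_TOL = 1e-10


@dataclass
class RigidTransform:
    """Physical-space map p -> R @ p + t (µm), with R proper orthonormal."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation must be proper (det = +1)")

    def apply_points(self, points_um: np.ndarray) -> np.ndarray:
        return np.asarray(points_um, dtype=float) @ self.rotation.T + self.translation

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()},
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        obj = json.loads(Path(path).read_text())
        return cls(np.asarray(obj["rotation"]), np.asarray(obj["translation"]))


def fit_cej_plane(
    points: CEJPointSet, apical_point_um: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA plane through the CEJ points.

    Returns (unit normal, centroid).  The normal is the principal
    direction of smallest variance; with exactly three points this
    coincides with the normalized cross product of the edge vectors.  If
    ``apical_point_um`` (typically the tooth center of mass) is given,
    the normal is oriented so that point lies on the +normal (apical)
    side; otherwise the sign makes the largest-magnitude component
    positive, which keeps the fit deterministic.
    """
    pts = points.points_um
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    if apical_point_um is not None:
        if float(np.dot(normal, np.asarray(apical_point_um) - centroid)) < 0:
            normal = -normal
    else:
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
    return normal / np.linalg.norm(normal), centroid


def orient_normal_apical(
    normal: np.ndarray, centroid: np.ndarray, tooth_points_um: np.ndarray
) -> np.ndarray:
    """Flip the plane normal so the root (apical) side of the tooth is +normal.

    The tooth extends much farther apically (root tips) than coronally
    (crown) from the CEJ, so the sign is chosen to put the larger signed
    extent of the tooth point cloud on the positive side.  This is robust
    even when the crown carries more volume than the tapered roots.
    """
    s = (np.asarray(tooth_points_um, dtype=float) - centroid) @ np.asarray(normal, dtype=float)
    return -np.asarray(normal) if float(s.max()) < float(-s.min()) else np.asarray(normal)


def transform_to_z(normal: np.ndarray, centroid: np.ndarray) -> RigidTransform:
    """Minimal rotation taking ``normal`` to (0, 0, 1), about the centroid.

    The translation places the CEJ centroid at the origin, so the CEJ
    plane becomes z = 0.  The in-plane (about-z) orientation is left
    arbitrary; the shell VOI and BV/TV are invariant to it.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, ez))
    v = np.cross(n, ez)
    sv = np.linalg.norm(v)
    if sv < 1e-12:
        if c > 0:
            rot = np.eye(3)
        else:  # normal = -z: 180 degrees about x
            rot = np.diag([1.0, -1.0, -1.0])
    else:
        # Rodrigues formula for the geodesic rotation n -> ez
        k = v / sv
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + sv * kx + (1 - c) * (kx @ kx)
    centroid = np.asarray(centroid, dtype=float)
    return RigidTransform(rot, -rot @ centroid)


def apply_transform(labelmap: LabelMap, transform: RigidTransform, background_label: int | None = None) -> LabelMap:
    """Resample a label map into the transformed frame (nearest neighbor).

    The output grid is enlarged to contain the rotated bounding box of
    the input; its ``origin_um`` records the physical coordinate of voxel
    (0, 0, 0) so downstream steps can locate the z = 0 CEJ plane.  Voxels
    mapping outside the input become ``background_label`` (default: the
    ``air`` label if present, else 0).
    """
    if background_label is None:
        try:
            background_label = labelmap.id_of("air")
        except KeyError:
            background_label = 0
    vs = labelmap.voxel_size_um
    shape = np.asarray(labelmap.shape)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)], dtype=float)
    corners_um = labelmap.origin_um + corners * vs
    tc = transform.apply_points(corners_um)
    # snap against float contamination so exact (identity / axis-permutation)
    # transforms resample without spurious half-voxel shifts
    lo_idx = np.floor(tc.min(axis=0) / vs + 1e-9)
    hi_idx = np.ceil(tc.max(axis=0) / vs - 1e-9)
    lo = lo_idx * vs
    out_shape = tuple((hi_idx - lo_idx).astype(int) + 1)
    rt = transform.rotation.T
    # input index = (R^T (out_origin + vs * out_index - t) - in_origin) / vs
    offset = (rt @ (lo - transform.translation) - labelmap.origin_um) / vs
    snap = np.round(offset)
    # integer offsets resample exactly; otherwise nudge off exact half-voxel
    # coordinates so nearest-neighbor rounding is uniform across the grid
    offset = np.where(np.abs(offset - snap) < 1e-9, snap, offset - 1e-4)
    out = ndi.affine_transform(
        labelmap.labels,
        rt,
        offset=offset,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=background_label,
        prefilter=False,
    )
    palette = dict(labelmap.palette)
    if background_label not in palette and background_label != 0:
        palette[background_label] = "air"
    return LabelMap(out.astype(labelmap.labels.dtype), palette, vs, lo)
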