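"""Bone volume fraction (BV/TV) inside the shell VOI."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .voi_builder import VOIShell
from .volume_io import LabelMap

__all__ = ["SiteID", "MorphometryResult", "compute_bv_tv", "compare_sites"]


@dataclass(frozen=True)
class SiteID:
    animal: str
    jaw: str = "upper"  # upper | lower
    side: str = "control"  # control | test (split-mouth role)


@dataclass
class MorphometryResult:
    bv_voxels: int
    tv_voxels: int
    bv_tv: float
    bv_mm3: float
    tv_mm3: float
    excluded_tooth_voxels: int
    voxel_size_um: float
    site: SiteID | None = None

    def to_dict(self) -> dict:
        d = {
            "bv_voxels": self.bv_voxels,
            "tv_voxels": self.tv_voxels,
            "bv_tv": self.bv_tv,
            "bv_mm3": self.bv_mm3,
            "tv_mm3": self.tv_mm3,
            "excluded_tooth_voxels": self.excluded_tooth_voxels,
            "voxel_size_um": self.voxel_size_um,
        }
        if self.site is not None:
            d.update(animal=self.site.animal, jaw=self.site.jaw, side=self.site.side)
        return d


def compute_bv_tv(shell: VOIShell, labels: LabelMap, site: SiteID | None = None) -> MorphometryResult:
    """Fraction of bone-labeled voxels within the shell VOI.

    TV is the shell minus any voxels carrying a tooth label (an adjacent
    tooth inside the shell is excluded from the reference volume rather
    than counted as missing bone; the excluded count is reported).  BV is
    the bone-labeled part of TV.
    """
    if shell.mask.shape != labels.shape:
        raise ValueError(f"shell grid {shell.mask.shape} does not match labels {labels.shape}")
    tooth = np.zeros(labels.shape, dtype=bool)
    for lid in labels.tooth_ids():
        tooth |= labels.labels == lid
    in_shell = shell.mask
    excluded = int((in_shell & tooth).sum())
    tv_mask = in_shell & ~tooth
    tv = int(tv_mask.sum())
    if tv == 0:
        raise ValueError("VOI contains no non-tooth voxels; TV = 0")
    bv = int((tv_mask & (labels.labels == labels.id_of("bone"))).sum())
    vox_mm3 = (labels.voxel_size_um * 1e-3) ** 3
    return MorphometryResult(
        bv_voxels=bv,
        tv_voxels=tv,
        bv_tv=bv / tv,
        bv_mm3=bv * vox_mm3,
        tv_mm3=tv * vox_mm3,
        excluded_tooth_voxels=excluded,
        voxel_size_um=labels.voxel_size_um,
        site=site,
    )


def compare_sites(results: Sequence[MorphometryResult]) -> pd.DataFrame:
    """Pair test/control results per (animal, jaw) into a long-format table.

    Each (animal, jaw) must contribute exactly one ``test`` and one
    ``control`` result; anything unpaired is an error.  The difference
    column is test minus control.
    """
    groups: dict[tuple[str, str], dict[str, MorphometryResult]] = {}
    for r in results:
        if r.site is None:
            raise ValueError("every result needs a SiteID for pairing")
        key = (r.site.animal, r.site.jaw)
        slot = groups.setdefault(key, {})
        if r.site.side in slot:
            raise ValueError(f"duplicate {r.site.side} result for animal {key}")
        slot[r.site.side] = r
    rows = []
    for (animal, jaw), slot in sorted(groups.items()):
        if set(slot) != {"test", "control"}:
            raise ValueError(f"unpaired record for animal {animal} ({jaw}): sides {sorted(slot)}")
        t, c = slot["test"], slot["control"]
        rows.append(
            {
                "animal": animal,
                "jaw": jaw,
                "bv_tv_test": t.bv_tv,
                "bv_tv_control": c.bv_tv,
                "difference": t.bv_tv - c.bv_tv,
            }
        )
    return pd.DataFrame(rows)
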