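"""Synthetic micro-CT jaw-quadrant phantoms with known ground truth.

A phantom emulates the content of a murine first-molar scan: a crown with
an enclosed pulp chamber, three tapered roots carrying open root canals,
a periodontal-ligament (PDL) gap of air intensity around the roots, and
trabecular alveolar bone with an exactly controlled volume fraction.
Tissue intensities are drawn with configurable spread so that, as in real
scans, the bone and dentin histograms overlap and plain global
thresholding fails while seeded watershed does not.

Every generator is a pure function of its spec (including the seed), so
studies are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .morphometry import compute_bv_tv
from .voi_builder import VOIShell, RootMask, build_voi
from .volume_io import CEJPointSet, LabelMap, Seed, SeedSet, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_trabecular_field",
    "generate_quadrant",
    "SplitMouthStudy",
    "generate_split_mouth_study",
    "reduced_phantom_spec",
]

AIR, BONE, TOOTH = 1, 2, 3
PALETTE = {AIR: "air", BONE: "bone", TOOTH: "tooth"}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic quadrant.

    Geometric fractions are relative to the grid extent so a spec scales
    coherently to reduced grids; physical parameters (PDL gap, dilation
    radius, correlation length) stay in µm.  Intensities are arbitrary
    units emulating reconstructed attenuation.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 10.4
    side: str = "right"
    seed: int = 0
    # tooth geometry (fractions)
    cej_z_frac: float = 0.32
    crown_height_frac: float = 0.22
    crown_radius_frac: float = 0.30  # of min transverse extent
    trunk_height_frac: float = 0.06
    root_length_frac: float = 0.50  # apical of the CEJ
    root_radius_frac: float = 0.45  # of crown radius
    root_taper: float = 0.35  # tip radius / cervical radius
    root_spread_frac: float = 0.55  # root-axis offset, of crown radius
    canal_radius_frac: float = 0.30  # of local root radius
    # periodontium and bone
    pdl_gap_um: float = 40.0
    target_bone_fraction: float = 0.62
    correlation_length_um: float = 120.0
    # intensity model: per-tissue mean + smooth within-tissue heterogeneity
    # (mineralization gradients; makes the bone and dentin histograms
    # overlap without destroying local edges) + voxel noise + blur
    air_mean: float = 20.0
    air_sd: float = 3.0
    bone_mean: float = 100.0
    bone_sd: float = 4.0
    tooth_mean: float = 140.0
    tooth_sd: float = 4.0
    heterogeneity_sd: float = 18.0  # amplitude of the smooth bias, bone and tooth
    heterogeneity_corr_um: float = 150.0
    blur_sigma_um: float = 4.0
    noise_sd: float = 5.0
    cej_jitter_voxels: float = 1.0  # sub-voxel scatter of the picked CEJ points
    # orthodontic treatment effect (bone loss concentrated mesially)
    treated: bool = False
    treatment_reduction: float = 0.8
    # minimum trabecular feature size (voxels); smaller pores/islets are
    # absorbed so every rendered structure is resolvable at the nominal
    # scan resolution, as in a real reconstruction
    min_feature_voxels: int = 150
    # VOI contract used for the ground truth
    crop_offset_voxels: int = 30
    dilation_radius_um: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.target_bone_fraction < 1:
            raise ValueError("target_bone_fraction must lie strictly in (0, 1)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.cej_z_frac + self.root_length_frac > 0.95:
            raise ValueError("root geometry exceeds the grid")
        if min(self.shape) < 16:
            raise ValueError("grid too small for a molar phantom")


def reduced_phantom_spec(**overrides) -> "PhantomSpec":
    """Spec for simulation studies: same ~1 mm quadrant on a coarser grid.

    A 56-voxel cube at 17.8 µm covers the same physical extent as the
    full-resolution phantom; the crop offset becomes 18 voxels (320 µm,
    matching the 30-voxel/312 µm full-resolution offset) and the CEJ pick
    scatter stays ~10 µm.  Pair with ``RunConfig(crop_offset_voxels=18)``.
    """
    defaults = dict(shape=(56, 56, 56), voxel_size_um=17.8, crop_offset_voxels=18, cej_jitter_voxels=0.6)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    label_map: LabelMap
    root_mask: RootMask
    voi_shell: VOIShell
    bv_tv: float
    cej_z_um: float


def _smooth_field(shape: tuple[int, int, int], correlation_length_um: float, voxel_size_um: float, rng: np.random.Generator) -> np.ndarray:
    """Correlated Gaussian random field (white noise, Gaussian-smoothed)."""
    noise = rng.standard_normal(shape)
    sigma_vox = max(correlation_length_um / (2.0 * voxel_size_um), 0.5)
    return ndi.gaussian_filter(noise, sigma=sigma_vox)


def _threshold_to_fraction(field: np.ndarray, region: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask selecting the top-``fraction`` field values inside region."""
    region_idx = np.flatnonzero(region.ravel())
    vals = field.ravel()[region_idx]
    k = int(round(fraction * vals.size))
    out = np.zeros(field.size, dtype=bool)
    if k >= vals.size:
        out[region_idx] = True
    elif k > 0:
        top = np.argpartition(vals, vals.size - k)[vals.size - k :]
        out[region_idx[top]] = True  # exactly k voxels even with value ties
    return out.reshape(field.shape)


def generate_trabecular_field(
    shape: tuple[int, int, int],
    target_fraction: float,
    correlation_length_um: float = 120.0,
    voxel_size_um: float = 10.4,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binary trabecular-like texture with an exact foreground fraction.

    A Gaussian random field with the given correlation length is
    thresholded at its empirical quantile, so the realized fraction
    matches ``target_fraction`` to within one voxel in the total count.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    if min(shape) < 1:
        raise ValueError("degenerate shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = _smooth_field(tuple(shape), correlation_length_um, voxel_size_um, rng)
    return _threshold_to_fraction(f, np.ones(shape, dtype=bool), target_fraction)


def _render_labels(spec: PhantomSpec) -> tuple[np.ndarray, float, np.ndarray]:
    """Truth labels for the *right*-side geometry, CEJ z (µm), mesial axis center."""
    n0, n1, n2 = spec.shape
    vs = spec.voxel_size_um
    Lx, Ly, Lz = n0 * vs, n1 * vs, n2 * vs
    x = np.arange(n0)[:, None, None] * vs
    y = np.arange(n1)[None, :, None] * vs
    z = np.arange(n2)[None, None, :] * vs
    cx, cy = (n0 - 1) * vs / 2.0, (n1 - 1) * vs / 2.0

    cej_idx = int(round(spec.cej_z_frac * n2))
    cej_z = cej_idx * vs
    crown_r = spec.crown_radius_frac * min(Lx, Ly)
    crown_bot = cej_z - spec.crown_height_frac * Lz
    trunk_bot = cej_z + spec.trunk_height_frac * Lz
    tip_z = cej_z + spec.root_length_frac * Lz
    r0 = spec.root_radius_frac * crown_r
    spread = spec.root_spread_frac * crown_r

    rxy2 = (x - cx) ** 2 + (y - cy) ** 2
    crown = (rxy2 <= crown_r**2) & (z >= crown_bot) & (z < cej_z)
    trunk = (rxy2 <= (0.85 * crown_r) ** 2) & (z >= cej_z) & (z < trunk_bot)

    # pulp chamber: ellipsoid enclosed in the crown
    ch_c = (crown_bot + cej_z) / 2.0
    ch_a, ch_b = 0.5 * crown_r, 0.35 * (cej_z - crown_bot)
    chamber = (rxy2 / ch_a**2 + (z - ch_c) ** 2 / ch_b**2) <= 1.0

    roots = np.zeros(spec.shape, dtype=bool)
    canals = np.zeros(spec.shape, dtype=bool)
    span = max(tip_z - trunk_bot, vs)
    frac = np.clip((z - trunk_bot) / span, 0.0, 1.0)
    radius_z = r0 * (1.0 - (1.0 - spec.root_taper) * frac)  # broadcast over z
    in_z = (z >= trunk_bot) & (z < tip_z)
    mesial_center = np.array([cx + spread, cy])
    for angle in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):  # mesial root at +x
        ax_, ay_ = cx + spread * np.cos(angle), cy + spread * np.sin(angle)
        d2 = (x - ax_) ** 2 + (y - ay_) ** 2
        roots |= (d2 <= radius_z**2) & in_z
        canal_r = np.maximum(spec.canal_radius_frac * radius_z, 1.05 * vs)
        canal_ok = radius_z >= 3.0 * vs  # canal must stay enclosed laterally
        canals |= (d2 <= canal_r**2) & in_z & canal_ok & (z < tip_z - 3 * vs)
    # canals continue coronally through the trunk/crown into the chamber
    for angle in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        ax_, ay_ = cx + spread * np.cos(angle), cy + spread * np.sin(angle)
        d2 = (x - ax_) ** 2 + (y - ay_) ** 2
        canals |= (d2 <= (spec.canal_radius_frac * r0) ** 2) & (z >= ch_c) & (z < trunk_bot)

    tooth = (crown | trunk | roots) & ~(chamber | canals)

    dist_to_tooth = ndi.distance_transform_edt(~tooth, sampling=vs)
    pdl = (dist_to_tooth > 0) & (dist_to_tooth <= spec.pdl_gap_um) & (z >= cej_z)

    alveolar = (z >= cej_z) & ~tooth & ~pdl
    rng = np.random.default_rng(spec.seed)
    f = _smooth_field(spec.shape, spec.correlation_length_um, vs, rng)
    # Calibrate the threshold inside the peri-root measurement sleeve (the
    # bone-bearing part of the future shell VOI), then apply it to the whole
    # alveolar region for a seamless texture.  This way the realized bone
    # fraction where BV/TV is measured tracks the requested target instead
    # of drifting with the texture realization.
    crop_z = cej_z + spec.crop_offset_voxels * vs
    sleeve = alveolar & (dist_to_tooth <= spec.dilation_radius_um) & (z >= crop_z)
    calib = sleeve if sleeve.sum() >= 100 else alveolar
    in_sleeve = _threshold_to_fraction(f, calib, spec.target_bone_fraction)
    kth = f[in_sleeve].min() if in_sleeve.any() else np.inf
    bone = alveolar & (f >= kth) if np.isfinite(kth) else np.zeros_like(alveolar)
    bone[calib] = in_sleeve[calib]

    if spec.treated:
        # bone loss concentrated around the mesial root
        influence = r0 + spec.pdl_gap_um + 4.0 * spec.dilation_radius_um / 2.5
        d2m = (x - mesial_center[0]) ** 2 + (y - mesial_center[1]) ** 2
        zone = alveolar & (d2m <= influence**2)
        local_target = spec.treatment_reduction * spec.target_bone_fraction
        bone[zone] = _threshold_to_fraction(f, zone, local_target)[zone]

    if spec.min_feature_voxels > 0:
        # absorb sub-resolution pores and bone islets (a real reconstruction
        # cannot carry structures below the scanner's resolving power)
        for src_mask, value in ((alveolar & ~bone, True), (bone, False)):
            comp, ncomp = ndi.label(src_mask)
            if ncomp:
                sizes = np.bincount(comp.ravel())
                small = np.flatnonzero(sizes < spec.min_feature_voxels)
                small = small[small > 0]
                if small.size:
                    bone[np.isin(comp, small)] = value

    labels = np.full(spec.shape, AIR, dtype=np.int32)
    labels[bone] = BONE
    labels[tooth] = TOOTH
    return labels, cej_z, mesial_center


def _interior_seeds(labels: np.ndarray, stride: int = 4, min_depth: float = 2.0) -> list[Seed]:
    """Liberal interior marking of every tissue, as a human operator would.

    Two kinds of markers per tissue: a coarse lattice of interior voxels
    (at least ``min_depth`` voxels from the tissue boundary, every
    ``stride`` voxels — the equivalent of brush strokes through the
    slices), plus the deepest voxel of every connected component, so that
    isolated pockets (e.g. marrow spaces fully enclosed by bone) are
    marked even when the lattice misses them.
    """
    seeds: list[Seed] = []
    for lid, name in PALETTE.items():
        mask = labels == lid
        if not mask.any():
            continue
        edt = ndi.distance_transform_edt(mask)
        deep = edt >= min_depth
        lattice = np.zeros_like(mask)
        lattice[::stride, ::stride, ::stride] = True
        for pos in np.argwhere(deep & lattice):
            seeds.append(Seed(name, tuple(int(c) for c in pos)))
        for region in (mask, deep):
            if not region.any():
                continue
            comp, ncomp = ndi.label(region)
            positions = ndi.maximum_position(edt, labels=comp, index=range(1, ncomp + 1))
            for pos in positions:
                seeds.append(Seed(name, tuple(int(c) for c in pos)))
    return seeds


def _cej_ring(spec: PhantomSpec, cej_z: float, rng: np.random.Generator, n_points: int = 12) -> CEJPointSet:
    vs = spec.voxel_size_um
    n0, n1, _ = spec.shape
    cx, cy = (n0 - 1) * vs / 2.0, (n1 - 1) * vs / 2.0
    crown_r = spec.crown_radius_frac * min(n0, n1) * vs
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    pts = np.column_stack(
        [cx + crown_r * np.cos(theta), cy + crown_r * np.sin(theta), np.full(n_points, cej_z)]
    )
    if spec.cej_jitter_voxels > 0:  # sub-voxel placement scatter of manual picks
        pts += rng.uniform(-1.0, 1.0, pts.shape) * vs * spec.cej_jitter_voxels
    return CEJPointSet(pts)


def generate_quadrant(spec: PhantomSpec) -> tuple[Volume, PhantomTruth, SeedSet, CEJPointSet]:
    """Render a phantom quadrant: volume, ground truth, seeds and CEJ points.

    The left side is the exact mirror (axis 0 flip) of the right-side
    geometry with the same seed.
    """
    labels, cej_z, _ = _render_labels(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))

    means = np.array([0.0, spec.air_mean, spec.bone_mean, spec.tooth_mean])
    sds = np.array([0.0, spec.air_sd, spec.bone_sd, spec.tooth_sd])
    vol = means[labels] + sds[labels] * rng.standard_normal(labels.shape)
    if spec.heterogeneity_sd > 0:
        # independent smooth bias per calcified tissue (normalized to unit sd)
        for lid in (BONE, TOOTH):
            bias = _smooth_field(labels.shape, spec.heterogeneity_corr_um, spec.voxel_size_um, rng)
            sd = bias.std()
            if sd > 0:
                vol += np.where(labels == lid, spec.heterogeneity_sd * bias / sd, 0.0)
    if spec.blur_sigma_um > 0:
        vol = ndi.gaussian_filter(vol, sigma=spec.blur_sigma_um / spec.voxel_size_um)
    if spec.noise_sd > 0:
        vol = vol + spec.noise_sd * rng.standard_normal(labels.shape)

    if spec.side == "left":
        labels = labels[::-1].copy()
        vol = vol[::-1].copy()

    label_map = LabelMap(labels, dict(PALETTE), spec.voxel_size_um)
    seeds = SeedSet(_interior_seeds(labels))
    cej = _cej_ring(spec, cej_z, rng)
    if spec.side == "left":
        pts = cej.points_um.copy()
        pts[:, 0] = (spec.shape[0] - 1) * spec.voxel_size_um - pts[:, 0]
        cej = CEJPointSet(pts)

    root_mask, shell = build_voi(
        label_map,
        cej_z_um=cej_z,
        crop_offset_voxels=spec.crop_offset_voxels,
        dilation_radius_um=spec.dilation_radius_um,
    )
    truth_bvtv = compute_bv_tv(shell, label_map).bv_tv
    truth = PhantomTruth(label_map, root_mask, shell, truth_bvtv, cej_z)
    return Volume(vol.astype(np.float32), spec.voxel_size_um), truth, seeds, cej


@dataclass
class SplitMouthStudy:
    """Per-animal paired phantom specs plus the generating truth table."""

    animals: list[tuple[PhantomSpec, PhantomSpec]]  # (control, test) per animal
    truth_table: pd.DataFrame

    def __iter__(self) -> Iterator[tuple[PhantomSpec, PhantomSpec]]:
        return iter(self.animals)

    def __len__(self) -> int:
        return len(self.animals)


def generate_split_mouth_study(
    n_animals: int = 14,
    control_mean: float = 0.4133,
    control_sd: float = 0.0491,
    test_mean: float = 0.3323,
    test_sd: float = 0.0574,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> SplitMouthStudy:
    """Paired treated/untreated phantom specs for a split-mouth experiment.

    Per animal the untreated (control, left) bone fraction is drawn from
    N(control_mean, control_sd) and the treated (test, right) fraction
    from N(test_mean, test_sd); defaults reproduce the protraction study
    conditions (control 41.33% +/- 4.91%, test 33.23% +/- 5.74%).  Drawn
    fractions are clipped to (0.02, 0.98).
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    if control_sd < 0 or test_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    animals = []
    rows = []
    for i in range(n_animals):
        fc = float(np.clip(rng.normal(control_mean, control_sd), 0.02, 0.98))
        ft = float(np.clip(rng.normal(test_mean, test_sd), 0.02, 0.98))
        sc = int(np.random.SeedSequence([seed, i, 0]).generate_state(1)[0] % (2**31))
        st = int(np.random.SeedSequence([seed, i, 1]).generate_state(1)[0] % (2**31))
        control = replace(base, side="left", target_bone_fraction=fc, seed=sc, treated=False)
        test = replace(base, side="right", target_bone_fraction=ft, seed=st, treated=False)
        animals.append((control, test))
        rows.append(
            {"animal": f"A{i + 1:02d}", "control_fraction": fc, "test_fraction": ft, "difference": ft - fc}
        )
    return SplitMouthStudy(animals, pd.DataFrame(rows))
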