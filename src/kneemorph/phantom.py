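"""Paired CT/MRI knee phantoms with exact geometric ground truth.

The phantom is built from primitives that match the measurement model of
the thickness protocol, so ground truth is known analytically:

* each femoral condyle is a cylinder segment whose axis is perpendicular
  to the sagittal plane, carrying a concentric cartilage shell over an
  inferior arc;
* the tibial plateau is a slab with a planar cartilage layer on top,
  split into medial and lateral parts;
* the trochlea is an anterior block on the femur with a planar cartilage
  slab facing the patella, and the patella a block whose posterior face
  carries the patellar cartilage (both uniform along the axial direction,
  so any in-range femoropatellar slice reads the same thickness);
* the fibula is a small vertical cylinder on the lateral side.

Both volumes are stored on the same quantitative HU-like scale (the fused
dataset extracts radiodensity in HU); the "MRI" volume is the same
analytic geometry rendered in a frame that is rigidly misaligned from the
CT frame by a known transform, with its own noise realisation. Cartilage
truth masks live in the MRI frame (cartilage is segmented from MRI), bone
masks in the CT frame, and paired landmarks are provided in both frames.

An optional one-voxel partial-volume rim at elevated HU is painted on the
cartilage boundary to emulate the intensity blending that the
erosion-plus-HU-window density step is designed to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grids import Mask, VoxelGrid
from .register import RigidTransform

BONE_PART_NAMES = ("femur", "tibia", "patella", "fibula")
CARTILAGE_PART_NAMES = (
    "femoral_cartilage",
    "lateral_tibial_cartilage",
    "medial_tibial_cartilage",
    "patellar_cartilage",
)

#: condylar cartilage arc (degrees, negative anterior / positive posterior
#: of the inferior direction)
ARC_DEG = (-60.0, 75.0)


@dataclass
class PhantomConfig:
    """Geometry, intensity and misalignment parameters of the phantom.

    ``cartilage_thickness`` may be a scalar (mm) or a callable of the
    condylar angle in radians (relative to the inferior direction, positive
    posterior) returning mm.
    """

    voxel_spacing: tuple[float, float, float] = (0.6, 0.6, 0.6)
    condyle_radius: float = 18.0
    # default thicknesses are whole-voxel multiples of the default 0.6 mm
    # spacing, keeping slab binarization error well inside half a voxel
    cartilage_thickness: float | Callable[[np.ndarray], np.ndarray] = 3.0
    tibial_cartilage_thickness: float = 2.4
    patellar_cartilage_thickness: float = 2.4
    trochlear_cartilage_thickness: float = 1.8
    tissue_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "background": (30.0, 15.0),
            "bone": (445.0, 150.0),
            "cartilage": (100.0, 10.0),
            "rim": (400.0, 30.0),
        }
    )
    #: MRI -> CT misalignment: intrinsic xyz Euler angles (deg) + translation (mm)
    misalignment: tuple[float, float, float, float, float, float] = (2.0, -1.5, 3.0, 4.0, -3.0, 2.0)
    landmark_count: int = 6
    landmark_noise_mm: float = 0.0
    partial_volume_rim: bool = True
    noise_seed: int = 0

    def validate(self) -> None:
        if np.any(np.asarray(self.voxel_spacing) <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.landmark_count < 3:
            raise ValueError("landmark_count must be >= 3")
        for t in (self.tibial_cartilage_thickness, self.patellar_cartilage_thickness,
                  self.trochlear_cartilage_thickness):
            if t <= 0:
                raise ValueError("cartilage thickness must be positive")

    def femoral_thickness(self, theta_rad: np.ndarray) -> np.ndarray:
        if callable(self.cartilage_thickness):
            return np.asarray(self.cartilage_thickness(theta_rad), dtype=float)
        return np.full_like(np.asarray(theta_rad, dtype=float), float(self.cartilage_thickness))


@dataclass
class PhantomSet:
    """A rendered phantom with its complete ground truth."""

    ct: VoxelGrid
    mri: VoxelGrid
    truth_masks_ct: dict[str, Mask]  # bones (+ all parts, CT frame)
    truth_masks_mri: dict[str, Mask]  # cartilages (+ trochlear aux, MRI frame)
    truth_thickness: dict[tuple[str, str, str], float]
    landmarks_ct: np.ndarray
    landmarks_mri: np.ndarray
    truth_transform: RigidTransform  # MRI frame -> CT frame
    truth_fpc_slice: int
    layout: dict[str, float]


class _Layout:
    """Derived world-coordinate layout (mm) of all phantom parts."""

    def __init__(self, config: PhantomConfig):
        radius = config.condyle_radius
        t_max = float(np.max(config.femoral_thickness(
            np.deg2rad(np.linspace(*ARC_DEG, 181)))))
        t_tib = config.tibial_cartilage_thickness
        self.cond_w = 24.0
        self.mc_x = (6.0, 6.0 + self.cond_w)
        self.lc_x = (38.0, 38.0 + self.cond_w)
        self.fibula_center = (68.5, 30.0)
        self.fibula_r = 3.5
        self.tibia_z = (4.0, 26.0)
        self.tib_cart_z = (26.0, 26.0 + t_tib)
        self.axis_yz = (30.0, self.tib_cart_z[1] + 2.0 + radius + t_max)
        self.radius = radius
        z_c = self.axis_yz[1]
        shell_tip_y = self.axis_yz[0] + (radius + t_max) * np.sin(np.deg2rad(-ARC_DEG[0]))
        self.troch_bone_y = (max(self.axis_yz[0] + radius, shell_tip_y) + 1.5, 0.0)
        self.troch_bone_y = (self.troch_bone_y[0], self.troch_bone_y[0] + 6.0)
        self.troch_cart_y = (self.troch_bone_y[1],
                             self.troch_bone_y[1] + config.trochlear_cartilage_thickness)
        pat_cart_outer = self.troch_cart_y[1] + 2.0
        self.pat_cart_y = (pat_cart_outer, pat_cart_outer + config.patellar_cartilage_thickness)
        self.pat_bone_y = (self.pat_cart_y[1], self.pat_cart_y[1] + 8.0)
        self.fpc_z = (z_c - 10.0, z_c + 10.0)
        self.troch_x = (8.0, 60.0)
        self.pat_x = (14.0, 54.0)
        self.tibia_x = (6.0, 62.0)
        self.tibia_y = (12.0, 48.0)
        self.tib_cart_y = (16.0, 44.0)
        self.extent = (
            75.0,
            self.pat_bone_y[1] + 3.0,
            z_c + radius + 3.0,
        )


def _condyle_polar(Y, Z, layout: _Layout):
    dy = Y - layout.axis_yz[0]
    dz = Z - layout.axis_yz[1]
    r = np.hypot(dy, dz)
    theta = np.arctan2(-dy, -dz)  # 0 at inferior, positive posterior
    return r, theta


def _part_masks(X, Y, Z, config: PhantomConfig, layout: _Layout) -> dict[str, np.ndarray]:
    """Evaluate the analytic tissue geometry at world coordinates (CT frame)."""
    lo, hi = np.deg2rad(ARC_DEG[0]), np.deg2rad(ARC_DEG[1])
    r, theta = _condyle_polar(Y, Z, layout)
    in_mc = (X >= layout.mc_x[0]) & (X < layout.mc_x[1])
    in_lc = (X >= layout.lc_x[0]) & (X < layout.lc_x[1])
    in_cond_x = in_mc | in_lc
    disc = in_cond_x & (r < layout.radius)

    t_theta = config.femoral_thickness(theta)
    in_arc = (theta >= lo) & (theta <= hi)
    shell = in_cond_x & in_arc & (r >= layout.radius) & (r < layout.radius + t_theta)

    troch_bone = (
        (X >= layout.troch_x[0]) & (X < layout.troch_x[1])
        & (Y >= layout.troch_bone_y[0]) & (Y < layout.troch_bone_y[1])
        & (Z >= layout.fpc_z[0]) & (Z < layout.fpc_z[1])
    )
    # both femoropatellar cartilages are uniform along z, so the thickness
    # read-out is independent of the axial slice the selection rule picks
    # (ties resolve to the lowest in-range slice)
    troch_cart = (
        (X >= layout.troch_x[0]) & (X < layout.troch_x[1])
        & (Y >= layout.troch_cart_y[0])
        & (Y < layout.troch_cart_y[0] + config.trochlear_cartilage_thickness)
        & (Z >= layout.fpc_z[0]) & (Z < layout.fpc_z[1])
    )
    pat_cart = (
        (X >= layout.pat_x[0]) & (X < layout.pat_x[1])
        & (Y > layout.pat_cart_y[1] - config.patellar_cartilage_thickness)
        & (Y <= layout.pat_cart_y[1])
        & (Z >= layout.fpc_z[0]) & (Z < layout.fpc_z[1])
    )
    pat_bone = (
        (X >= layout.pat_x[0]) & (X < layout.pat_x[1])
        & (Y > layout.pat_bone_y[0]) & (Y <= layout.pat_bone_y[1])
        & (Z >= layout.fpc_z[0]) & (Z < layout.fpc_z[1])
    )
    tibia = (
        (X >= layout.tibia_x[0]) & (X < layout.tibia_x[1])
        & (Y >= layout.tibia_y[0]) & (Y < layout.tibia_y[1])
        & (Z >= layout.tibia_z[0]) & (Z < layout.tibia_z[1])
    )
    tib_cart_common = (
        (Y >= layout.tib_cart_y[0]) & (Y < layout.tib_cart_y[1])
        & (Z >= layout.tib_cart_z[0]) & (Z < layout.tib_cart_z[1])
    )
    mt_cart = tib_cart_common & (X >= layout.mc_x[0] + 2) & (X < layout.mc_x[1] - 2)
    lt_cart = tib_cart_common & (X >= layout.lc_x[0] + 2) & (X < layout.lc_x[1] - 2)
    fibula = (
        (np.hypot(X - layout.fibula_center[0], Y - layout.fibula_center[1]) < layout.fibula_r)
        & (Z >= layout.tibia_z[0]) & (Z < layout.tibia_z[1])
    )
    return {
        "femur": disc | troch_bone,
        "tibia": tibia,
        "patella": pat_bone,
        "fibula": fibula,
        "femoral_cartilage": shell | troch_cart,
        "lateral_tibial_cartilage": lt_cart,
        "medial_tibial_cartilage": mt_cart,
        "patellar_cartilage": pat_cart,
        "trochlear_cartilage": troch_cart,
    }


def _render(masks: dict[str, np.ndarray], config: PhantomConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Paint tissue HU (with Gaussian noise) into a volume."""
    from scipy import ndimage

    shape = masks["femur"].shape
    mean, sd = config.tissue_hu["background"]
    vol = rng.normal(mean, sd, size=shape)
    bone = np.zeros(shape, dtype=bool)
    for name in BONE_PART_NAMES:
        bone |= masks[name]
    cart = np.zeros(shape, dtype=bool)
    for name in CARTILAGE_PART_NAMES:
        cart |= masks[name]
    mean, sd = config.tissue_hu["cartilage"]
    vol[cart] = rng.normal(mean, sd, size=int(cart.sum()))
    if config.partial_volume_rim:
        struct = ndimage.generate_binary_structure(3, 1)
        interior = ndimage.binary_erosion(cart, structure=struct)
        rim = cart & ~interior
        mean, sd = config.tissue_hu["rim"]
        vol[rim] = rng.normal(mean, sd, size=int(rim.sum()))
    mean, sd = config.tissue_hu["bone"]
    vol[bone] = rng.normal(mean, sd, size=int(bone.sum()))
    return vol


def _truth_thickness(config: PhantomConfig) -> dict[tuple[str, str, str], float]:
    from .thickness import MEDIAL_ZERO_OFFSET_DEG, REGION_CENTERS

    truth: dict[tuple[str, str, str], float] = {}
    for comp, offset in (("medial", -MEDIAL_ZERO_OFFSET_DEG), ("lateral", 0.0)):
        for point, angle in REGION_CENTERS.items():
            theta = np.deg2rad(angle + offset)
            truth[(comp, "femur", point)] = float(config.femoral_thickness(np.array(theta)))
        for point in ("anterior", "middle", "posterior"):
            truth[(comp, "tibia", point)] = config.tibial_cartilage_thickness
    for point in ("medial", "center", "lateral"):
        truth[("femoropatellar", "patella", point)] = config.patellar_cartilage_thickness
    for point in ("medial", "lateral"):
        truth[("femoropatellar", "trochlea", point)] = config.trochlear_cartilage_thickness
    return truth


def _landmarks(layout: _Layout, count: int) -> np.ndarray:
    z_c = layout.axis_yz[1]
    pts = [
        (np.mean(layout.mc_x), layout.axis_yz[0], z_c + layout.radius),
        (np.mean(layout.lc_x), layout.axis_yz[0], z_c + layout.radius),
        (layout.fibula_center[0], layout.fibula_center[1], layout.tibia_z[1]),
        (np.mean(layout.pat_x), layout.pat_bone_y[1], z_c),
        (layout.tibia_x[0], layout.tibia_y[0], layout.tibia_z[0]),
        (layout.troch_x[0], layout.troch_bone_y[0], layout.fpc_z[0]),
        (layout.tibia_x[1], layout.tibia_y[1], layout.tibia_z[0]),
        (np.mean(layout.mc_x), layout.axis_yz[0] - layout.radius, z_c),
    ]
    if count > len(pts):
        raise ValueError(f"at most {len(pts)} landmarks available")
    return np.array(pts[:count], dtype=float)


def generate_phantom(config: PhantomConfig | None = None) -> PhantomSet:
    """Render the paired CT/MRI phantom with complete ground truth.

    Raises ValueError ("unresolvable geometry") if any configured cartilage
    thickness is below one voxel.
    """
    config = config or PhantomConfig()
    config.validate()
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    theta_grid = np.deg2rad(np.linspace(*ARC_DEG, 181))
    min_t = min(
        float(np.min(config.femoral_thickness(theta_grid))),
        config.tibial_cartilage_thickness,
        config.patellar_cartilage_thickness,
        config.trochlear_cartilage_thickness,
    )
    if min_t < float(np.max(spacing)):
        raise ValueError(
            f"unresolvable geometry: cartilage thickness {min_t:g} mm is below "
            f"one voxel ({np.max(spacing):g} mm)"
        )
    layout = _Layout(config)
    # 6 mm margin on every side keeps the misaligned MRI rendering of the
    # geometry inside the field of view
    margin = 6.0
    origin = np.full(3, -margin)
    shape = tuple(
        int(np.ceil((e + 2 * margin) / s)) for e, s in zip(layout.extent, spacing)
    )
    axes = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)

    rng = np.random.default_rng(config.noise_seed)
    rng_ct, rng_mri = rng.spawn(2)

    masks_ct_bool = _part_masks(X, Y, Z, config, layout)
    ct_vol = _render(masks_ct_bool, config, rng_ct)

    # rotate about the volume center (not the corner) so the misalignment
    # displaces structures by roughly the configured translation only
    center = origin + np.asarray(layout.extent) / 2.0
    euler = RigidTransform.from_euler(config.misalignment[:3], (0.0, 0.0, 0.0))
    transform = RigidTransform(
        euler.rotation,
        center - euler.rotation @ center + np.asarray(config.misalignment[3:], float),
    )
    # MRI voxel at p sees the CT-frame geometry at T(p)
    rot, trans = transform.rotation, transform.translation
    Xc = rot[0, 0] * X + rot[0, 1] * Y + rot[0, 2] * Z + trans[0]
    Yc = rot[1, 0] * X + rot[1, 1] * Y + rot[1, 2] * Z + trans[1]
    Zc = rot[2, 0] * X + rot[2, 1] * Y + rot[2, 2] * Z + trans[2]
    masks_mri_bool = _part_masks(Xc, Yc, Zc, config, layout)
    mri_vol = _render(masks_mri_bool, config, rng_mri)

    truth_masks_ct = {
        name: Mask(sel, spacing, origin) for name, sel in masks_ct_bool.items()
    }
    # cartilage is segmented from MRI; the femur is included so the
    # thickness protocol can find the bone-cartilage interface in-frame
    truth_masks_mri = {
        name: Mask(masks_mri_bool[name], spacing, origin)
        for name in CARTILAGE_PART_NAMES + ("trochlear_cartilage", "femur")
    }

    landmarks_ct = _landmarks(layout, config.landmark_count)
    landmarks_mri = transform.inverse().apply_points(landmarks_ct)
    if config.landmark_noise_mm > 0:
        noise_rng = np.random.default_rng(config.noise_seed + 1)
        landmarks_mri = landmarks_mri + noise_rng.normal(
            0.0, config.landmark_noise_mm, size=landmarks_mri.shape
        )

    # the CT-frame FPC cartilages are uniform in z, so every in-range slice
    # ties and the selection rule returns the lowest one
    kz = origin[2] + np.arange(shape[2]) * spacing[2]
    band = np.flatnonzero((kz >= layout.fpc_z[0]) & (kz < layout.fpc_z[1]))
    truth_fpc = int(band[0])

    return PhantomSet(
        ct=VoxelGrid(ct_vol, spacing, origin),
        mri=VoxelGrid(mri_vol, spacing, origin),
        truth_masks_ct=truth_masks_ct,
        truth_masks_mri=truth_masks_mri,
        truth_thickness=_truth_thickness(config),
        landmarks_ct=landmarks_ct,
        landmarks_mri=landmarks_mri,
        truth_transform=transform,
        truth_fpc_slice=truth_fpc,
        layout={"axis_y": layout.axis_yz[0], "axis_z": layout.axis_yz[1],
                "condyle_radius": layout.radius},
    )
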