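"""Articular cartilage thickness (ACT) protocol.

Femoral condyles: a cylinder with axis perpendicular to the sagittal plane
is fitted to the articular cartilage, which in a sagittal slice reduces to
a least-squares circle. Three 30-degree regions are laid out around a 0
degree reference ray: in the lateral compartment (LC) the reference points
at the most inferior point of the condyle; in the medial compartment (MC)
it sits 20 degrees anterior to that. The anterior region spans [-30, 0),
the middle [0, 30) and the posterior [30, 60] degrees (positive angles
posterior), and thickness is read radially at the three region centers
(-15, +15, +45 degrees). The compartment ACT is the arithmetic mean of the
three points.

Tibia: in the same sagittal slice an anteroposterior line spanning the
tibial cartilage is divided into three equal regions and thickness is read
perpendicular to the line at the region centers (1/6, 1/2, 5/6 of the
cartilage length).

Femoropatellar compartment (FPC): the axial slice where trochlear plus
patellar cartilage are jointly thickest is selected; the patella is probed
at three points (center plus the centers of the medial and lateral halves)
and the trochlea at two (center of the medial and of the lateral condylar
cartilage).

Slice conventions follow the canonical orientation of :mod:`kneemorph.grids`:
a sagittal slice is a (y, z) plane (+y anterior, +z superior) and an axial
slice is an (x, y) plane (+x from medial to lateral). Boundaries are
located at sub-voxel precision by linear interpolation of the binary mask
along the probing ray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

#: Angular region layout (degrees, positive = posterior of the 0-degree ray)
REGIONS = {"anterior": (-30.0, 0.0), "middle": (0.0, 30.0), "posterior": (30.0, 60.0)}
REGION_CENTERS = {"anterior": -15.0, "middle": 15.0, "posterior": 45.0}
#: MC 0-degree reference offset, anterior of the LC (most-inferior) reference
MEDIAL_ZERO_OFFSET_DEG = 20.0


@dataclass
class ThicknessMeasurement:
    """Thickness (mm) at one named measurement site."""

    compartment: str
    bone: str
    point: str
    thickness_mm: float


@dataclass
class CondyleFrame:
    """In-slice polar frame of one femoral condyle.

    ``center`` is the fitted circle center in (y, z) mm, ``zero_dir`` the
    unit direction of the 0-degree ray, and angles increase toward
    posterior (-y).
    """

    center: np.ndarray
    zero_dir: np.ndarray
    compartment: str

    @property
    def zero_angle(self) -> float:
        """Signed angle (radians) of the 0-degree ray from the inferior axis."""
        return float(np.arctan2(-self.zero_dir[0], -self.zero_dir[1]))

    def direction(self, angle_deg: float) -> np.ndarray:
        """Unit ray direction at ``angle_deg`` relative to the 0-degree ray."""
        a = -np.deg2rad(angle_deg)  # positive protocol angle rotates toward -y
        cos_a, sin_a = np.cos(a), np.sin(a)
        rot = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
        return rot @ self.zero_dir


def fit_condyle_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through in-slice cartilage points.

    Algebraic (Kasa) initialisation refined by geometric least squares.
    Returns (center (2,), radius, RMS radial residual).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9 * max(1.0, np.abs(centered).max()):
        raise ValueError("cannot fit a circle to collinear points")
    # Kasa: minimize ||a*y + b*z + c - (y^2+z^2)||
    design = np.column_stack([pts, np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    (a, b, c), *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center0 = np.array([a / 2.0, b / 2.0])
    radius0 = float(np.sqrt(c + center0 @ center0))

    def residuals(params):
        cy, cz, radius = params
        return np.hypot(pts[:, 0] - cy, pts[:, 1] - cz) - radius

    sol = optimize.least_squares(residuals, x0=[center0[0], center0[1], radius0])
    center = sol.x[:2]
    radius = float(sol.x[2])
    rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    return center, radius, rms


def condyle_frame(
    center: np.ndarray, compartment: str, most_inferior_point: np.ndarray
) -> CondyleFrame:
    """Build the angular frame of a condyle from its fitted circle.

    LC: the 0-degree ray points from the center to the most inferior
    condyle point. MC: that reference is rotated 20 degrees toward anterior.
    """
    compartment = compartment.upper()
    if compartment not in ("MC", "LC"):
        raise ValueError(f"unknown compartment {compartment!r}; expected 'MC' or 'LC'")
    center = np.asarray(center, dtype=float).reshape(2)
    inf_pt = np.asarray(most_inferior_point, dtype=float).reshape(2)
    direction = inf_pt - center
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("most inferior point coincides with the circle center")
    zero_dir = direction / norm
    if compartment == "MC":
        a = np.deg2rad(MEDIAL_ZERO_OFFSET_DEG)  # rotate toward anterior (+y)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        zero_dir = rot @ zero_dir
    return CondyleFrame(center=center, zero_dir=zero_dir, compartment=compartment)


def _sample_mask_line(
    mask2d: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a binary 2-D mask along a ray; returns (s, value)."""
    n = max(int(np.ceil(length / step)) + 1, 2)
    s = np.linspace(0.0, length, n)
    pts = start[None, :] + s[:, None] * direction[None, :]
    idx = (pts - origin[None, :]) / spacing[None, :]
    vals = ndimage.map_coordinates(
        mask2d.astype(np.float32), idx.T, order=1, mode="constant", cval=0.0
    )
    return s, vals


def _runs(s: np.ndarray, vals: np.ndarray, level: float = 0.5) -> list[tuple[float, float]]:
    """Contiguous above-level intervals of a sampled profile, with the
    interval ends refined by linear interpolation between samples."""
    inside = vals >= level
    if not inside.any():
        return []
    runs: list[tuple[float, float]] = []
    changes = np.flatnonzero(np.diff(inside.astype(np.int8)))
    starts = [0] if inside[0] else []
    ends: list[int] = []
    for c in changes:
        if inside[c + 1]:
            starts.append(c + 1)
        else:
            ends.append(c)
    if inside[-1]:
        ends.append(len(s) - 1)
    for i0, i1 in zip(starts, ends):
        if i0 > 0:
            frac = (level - vals[i0 - 1]) / (vals[i0] - vals[i0 - 1])
            lo = s[i0 - 1] + frac * (s[i0] - s[i0 - 1])
        else:
            lo = s[0]
        if i1 < len(s) - 1:
            frac = (level - vals[i1]) / (vals[i1 + 1] - vals[i1])
            hi = s[i1] + frac * (s[i1 + 1] - s[i1])
        else:
            hi = s[-1]
        runs.append((float(lo), float(hi)))
    return runs


def radial_thickness(
    frame: CondyleFrame,
    cartilage_slice: np.ndarray,
    spacing,
    origin,
    angle_deg: float,
    step_mm: float = 0.05,
) -> float:
    """Cartilage thickness along the radial ray at ``angle_deg``.

    The ray starts at the fitted axis and the thickness is the length of
    the (longest) cartilage crossing, with both boundaries located at
    sub-voxel precision.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    direction = frame.direction(angle_deg)
    extent = np.asarray(cartilage_slice.shape) * spacing
    length = float(np.linalg.norm(extent) + np.linalg.norm(frame.center - origin))
    s, vals = _sample_mask_line(
        cartilage_slice, spacing, origin, frame.center, direction, length, step_mm
    )
    runs = _runs(s, vals)
    if not runs:
        raise ValueError(f"no cartilage at angle {angle_deg:g} degrees")
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    return hi - lo


def _interface_points(
    cartilage_slice: np.ndarray, bone_slice: np.ndarray, spacing, origin
) -> np.ndarray:
    """(y, z) mm coordinates of cartilage voxels face-adjacent to bone."""
    struct = ndimage.generate_binary_structure(2, 1)
    near_bone = ndimage.binary_dilation(bone_slice, structure=struct)
    sel = cartilage_slice & near_bone
    idx = np.argwhere(sel)
    origin = np.asarray(origin, dtype=float).reshape(2)
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    return origin + idx * spacing


def femoral_act(
    cartilage_slice: np.ndarray,
    bone_slice: np.ndarray,
    spacing,
    origin,
    compartment: str,
) -> tuple[list[ThicknessMeasurement], float]:
    """Three-point femoral condyle thickness and its average for one slice.

    The circle is fitted to the bone-cartilage interface; the most inferior
    point of the condylar bone fixes the 0-degree reference (offset 20
    degrees anterior for MC); thickness is read at -15, +15 and +45 degrees.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    if not cartilage_slice.any():
        raise ValueError("femoral cartilage absent from slice")
    pts = _interface_points(cartilage_slice, bone_slice, spacing, origin)
    if len(pts) < 3:
        raise ValueError("too few bone-cartilage interface points for a circle fit")
    center, _, _ = fit_condyle_circle(pts)
    bone_idx = np.argwhere(bone_slice)
    bone_pts = origin + bone_idx * spacing
    zmin = bone_pts[:, 1].min()
    lowest = bone_pts[np.abs(bone_pts[:, 1] - zmin) < spacing[1] / 2]
    inferior_pt = np.array([lowest[:, 0].mean(), zmin])
    frame = condyle_frame(center, compartment, inferior_pt)
    measurements = []
    missing = []
    for name, angle in REGION_CENTERS.items():
        try:
            t = radial_thickness(frame, cartilage_slice, spacing, origin, angle)
        except ValueError:
            missing.append(name)
            continue
        comp = "medial" if frame.compartment == "MC" else "lateral"
        measurements.append(ThicknessMeasurement(comp, "femur", name, t))
    if missing:
        raise ValueError(f"no cartilage in region(s): {', '.join(missing)}")
    avg = float(np.mean([m.thickness_mm for m in measurements]))
    return measurements, avg


def tibial_act(
    cartilage_slice: np.ndarray, spacing, origin, compartment: str
) -> tuple[list[ThicknessMeasurement], float]:
    """Three-point tibial plateau thickness for one sagittal slice.

    The anteroposterior cartilage extent is split into three equal regions;
    thickness is read perpendicular to the AP line (along z) at the region
    centers. The anterior point sits at the +y end.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    if not cartilage_slice.any():
        raise ValueError("tibial cartilage absent from slice")
    occupied = np.flatnonzero(cartilage_slice.any(axis=1))
    if len(occupied) < 3:
        raise ValueError("tibial cartilage shorter than 3 voxels along the AP line")
    y0 = origin[0] + occupied[0] * spacing[0]
    y1 = origin[0] + occupied[-1] * spacing[0]
    length = y1 - y0
    z_extent = cartilage_slice.shape[1] * spacing[1]
    positions = {"posterior": y0 + length / 6.0, "middle": y0 + length / 2.0,
                 "anterior": y0 + 5.0 * length / 6.0}
    comp = "medial" if compartment.upper() == "MC" else "lateral"
    measurements = []
    for name in ("anterior", "middle", "posterior"):
        start = np.array([positions[name], origin[1]])
        s, vals = _sample_mask_line(
            cartilage_slice, spacing, origin, start, np.array([0.0, 1.0]), z_extent, 0.05
        )
        runs = _runs(s, vals)
        if not runs:
            raise ValueError(f"no tibial cartilage at the {name} point")
        lo, hi = max(runs, key=lambda r: r[1] - r[0])
        measurements.append(ThicknessMeasurement(comp, "tibia", name, hi - lo))
    avg = float(np.mean([m.thickness_mm for m in measurements]))
    return measurements, avg


def _column_thickness_profile(slice2d: np.ndarray, spacing, origin, x_mm: float) -> float:
    """Longest cartilage crossing along y at a given x position (mm)."""
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    y_extent = slice2d.shape[1] * spacing[1]
    start = np.array([x_mm, origin[1]])
    s, vals = _sample_mask_line(slice2d, spacing, origin, start, np.array([0.0, 1.0]),
                                y_extent, 0.05)
    runs = _runs(s, vals)
    if not runs:
        return 0.0
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    return hi - lo


def _max_slice_thickness(slice2d: np.ndarray, spacing) -> float:
    """Maximum per-column thickness (mm) in an axial slice, at voxel level."""
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    counts = slice2d.sum(axis=1)
    return float(counts.max() * spacing[1])


def select_fpc_slice(trochlea_mask: np.ndarray, patella_mask: np.ndarray, spacing) -> int:
    """Axial slice index where both FPC cartilages are jointly thickest.

    The score of slice k is the maximum trochlear column thickness plus the
    maximum patellar column thickness; ties break to the lowest index.
    """
    if not trochlea_mask.any() or not patella_mask.any():
        raise ValueError("trochlear and patellar cartilage masks must be non-empty")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    nz = trochlea_mask.shape[2]
    best_k, best_score = -1, -np.inf
    for k in range(nz):
        tro = trochlea_mask[:, :, k]
        pat = patella_mask[:, :, k]
        if not tro.any() or not pat.any():
            continue
        score = _max_slice_thickness(tro, spacing[:2]) + _max_slice_thickness(pat, spacing[:2])
        if score > best_score:  # strict: ties keep the lowest index
            best_score, best_k = score, k
    if best_k < 0:
        raise ValueError("no axial slice contains both FPC cartilages")
    return best_k


def patellar_act(
    cartilage_slice: np.ndarray, spacing, origin
) -> tuple[list[ThicknessMeasurement], float]:
    """Three-point patellar thickness in the selected axial slice.

    Points: the center of the cartilage arc (the patellar apex in this
    projection) and the centers of its medial and lateral halves; thickness
    is read normal to the subchondral boundary (along y for the slab/arc
    geometry used here).
    """
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    if not cartilage_slice.any():
        raise ValueError("patellar cartilage absent from slice")
    occupied = np.flatnonzero(cartilage_slice.any(axis=1))
    x0 = origin[0] + occupied[0] * spacing[0]
    x1 = origin[0] + occupied[-1] * spacing[0]
    length = x1 - x0
    points = {"medial": x0 + length / 4.0, "center": x0 + length / 2.0,
              "lateral": x0 + 3.0 * length / 4.0}
    measurements = []
    for name in ("medial", "center", "lateral"):
        t = _column_thickness_profile(cartilage_slice, spacing, origin, points[name])
        if t <= 0:
            raise ValueError(f"no patellar cartilage at the {name} point")
        measurements.append(ThicknessMeasurement("femoropatellar", "patella", name, t))
    avg = float(np.mean([m.thickness_mm for m in measurements]))
    return measurements, avg


def trochlear_act(
    cartilage_slice: np.ndarray, spacing, origin
) -> tuple[list[ThicknessMeasurement], float]:
    """Two-point trochlear thickness: centers of the medial and lateral
    condylar cartilage in the selected axial slice."""
    spacing = np.asarray(spacing, dtype=float).reshape(2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    if not cartilage_slice.any():
        raise ValueError("trochlear cartilage absent from slice")
    occupied = np.flatnonzero(cartilage_slice.any(axis=1))
    x_lo = origin[0] + occupied[0] * spacing[0]
    x_hi = origin[0] + occupied[-1] * spacing[0]
    mid = (x_lo + x_hi) / 2.0
    measurements = []
    for name, (lo, hi) in (("medial", (x_lo, mid)), ("lateral", (mid, x_hi))):
        cols = occupied[
            (origin[0] + occupied * spacing[0] >= lo) & (origin[0] + occupied * spacing[0] <= hi)
        ]
        if len(cols) == 0:
            raise ValueError(f"no trochlear cartilage in the {name} half")
        x_pt = origin[0] + (cols[0] + cols[-1]) / 2.0 * spacing[0]
        t = _column_thickness_profile(cartilage_slice, spacing, origin, x_pt)
        if t <= 0:
            raise ValueError(f"no trochlear cartilage at the {name} point")
        measurements.append(ThicknessMeasurement("femoropatellar", "trochlea", name, t))
    avg = float(np.mean([m.thickness_mm for m in measurements]))
    return measurements, avg


def measure_all_sites(masks: dict, spacing, origin=None) -> dict[tuple[str, str, str], float]:
    """Run the full 17-point thickness protocol on fused, per-part masks.

    Expects boolean 3-D arrays under keys ``femur``, ``femoral_cartilage``,
    ``medial_tibial_cartilage``, ``lateral_tibial_cartilage``,
    ``patellar_cartilage`` and ``trochlear_cartilage`` (the trochlear mask
    is the anterior portion of the femoral cartilage). The sagittal
    measurement slice of each femorotibial compartment is the mid-condylar
    slice of that compartment's cartilage; the FPC slice is selected by
    :func:`select_fpc_slice`. Returns a map (compartment, bone, point) ->
    thickness in mm.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float).reshape(3)
    fem_cart = masks["femoral_cartilage"] & ~masks.get(
        "trochlear_cartilage", np.zeros_like(masks["femoral_cartilage"])
    )
    femur = masks["femur"]
    results: dict[tuple[str, str, str], float] = {}

    occupied_x = np.flatnonzero(fem_cart.any(axis=(1, 2)))
    if len(occupied_x) == 0:
        raise ValueError("condylar femoral cartilage is empty")
    mid = (occupied_x[0] + occupied_x[-1]) / 2.0
    med_cols = occupied_x[occupied_x <= mid]
    lat_cols = occupied_x[occupied_x > mid]
    for comp_name, short, cols in (("medial", "MC", med_cols), ("lateral", "LC", lat_cols)):
        i = int(cols[len(cols) // 2])
        meas, _ = femoral_act(
            fem_cart[i], femur[i], spacing[1:], origin[1:], short
        )
        for m in meas:
            results[(comp_name, "femur", m.point)] = m.thickness_mm
        tib_key = f"{comp_name}_tibial_cartilage"
        tib = masks[tib_key]
        tib_x = np.flatnonzero(tib.any(axis=(1, 2)))
        j = int(tib_x[len(tib_x) // 2])
        tmeas, _ = tibial_act(tib[j], spacing[1:], origin[1:], short)
        for m in tmeas:
            results[(comp_name, "tibia", m.point)] = m.thickness_mm

    tro = masks["trochlear_cartilage"]
    pat = masks["patellar_cartilage"]
    k = select_fpc_slice(tro, pat, spacing)
    pmeas, _ = patellar_act(pat[:, :, k], spacing[:2], origin[:2])
    for m in pmeas:
        results[("femoropatellar", "patella", m.point)] = m.thickness_mm
    tmeas, _ = trochlear_act(tro[:, :, k], spacing[:2], origin[:2])
    for m in tmeas:
        results[("femoropatellar", "trochlea", m.point)] = m.thickness_mm
    return results
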