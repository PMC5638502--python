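"""Voxelized head phantoms and ellipsoidal blood lesions.

The canonical test phantom is a concentric layered sphere standing in
for a segmented MRI head: an outer skull shell, a CSF shell, a gray
matter shell, and a white matter core, with air outside.  Coordinates
are right-handed, in meters, with the phantom origin at the head
center; the antenna sits below the head on the -z axis and looks up
along +z.

Voxel membership uses a center-point test (no partial volumes): a voxel
belongs to a region iff its center does.  A loader for externally
supplied label grids is provided so a segmented head can be dropped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ML_PER_M3 = 1e6  # 1 m^3 = 1e6 ml

# canonical label assignment for generated phantoms
DEFAULT_LABEL_MAP = {
    0: "air",
    1: "skull",
    2: "csf",
    3: "gray_matter",
    4: "white_matter",
    5: "blood",
}
BLOOD_LABEL = 5


class ResolutionError(ValueError):
    """Voxel spacing too coarse to resolve the requested layers."""


@dataclass(frozen=True)
class HeadLayers:
    """Concentric-shell head geometry (meters)."""

    outer_radius: float = 0.090
    skull_thickness: float = 0.007
    csf_thickness: float = 0.003
    gray_thickness: float = 0.004
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        t = (self.skull_thickness, self.csf_thickness, self.gray_thickness)
        if any(x <= 0 for x in t) or self.outer_radius <= 0:
            raise ValueError("layer thicknesses and outer radius must be positive")
        if sum(t) >= self.outer_radius:
            raise ValueError("layer thicknesses must sum to less than outer radius")

    @property
    def skull_inner(self) -> float:
        return self.outer_radius - self.skull_thickness

    @property
    def csf_inner(self) -> float:
        return self.skull_inner - self.csf_thickness

    @property
    def gray_inner(self) -> float:
        return self.csf_inner - self.gray_thickness

    def brain_volume_weights(self) -> list:
        """(tissue, volume) pairs for gray shell and white core."""
        vg = self.csf_inner ** 3 - self.gray_inner ** 3
        vw = self.gray_inner ** 3
        return [("gray_matter", vg), ("white_matter", vw)]


@dataclass
class VoxelPhantom:
    """Regular 3-D grid of tissue labels.

    ``labels[i, j, k]`` covers the voxel whose center is
    ``origin + spacing * (i + 0.5, j + 0.5, k + 0.5)``.
    """

    spacing: float                 # m, isotropic
    origin: np.ndarray             # (3,) m, corner of voxel (0,0,0)
    labels: np.ndarray             # 3-D int array
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3-D grid")
        missing = set(np.unique(self.labels)) - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_map")

    @property
    def shape(self):
        return self.labels.shape

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (N, 3) of voxel centers, optionally masked."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.origin + self.spacing * (idx + 0.5)

    def tissue_of(self, label: int) -> str:
        return self.label_map[label]

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(self.spacing, self.origin.copy(),
                            self.labels.copy(), dict(self.label_map))


@dataclass(frozen=True)
class EllipsoidLesion:
    """Blood lesion: center of gravity, semi-axes and orientation.

    ``rotation`` maps lesion-frame coordinates to world frame and must
    be a proper rotation (orthonormal, det +1).  The analytic volume is
    (4/3) pi a b c.
    """

    center: tuple
    semi_axes: tuple          # (a, b, c) m
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    tissue: str = "blood"

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if not self.is_empty:
            if any(s <= 0 for s in self.semi_axes):
                raise ValueError("semi-axes must be positive (or all zero for empty)")
            if (not np.allclose(R @ R.T, np.eye(3), atol=1e-10)
                    or not np.isclose(np.linalg.det(R), 1.0, atol=1e-10)):
                raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)

    @property
    def is_empty(self) -> bool:
        return all(s == 0 for s in self.semi_axes)

    @property
    def volume_m3(self) -> float:
        a, b, c = self.semi_axes
        return (4.0 / 3.0) * np.pi * a * b * c

    @property
    def volume_ml(self) -> float:
        return self.volume_m3 * ML_PER_M3

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which world points lie inside the ellipsoid."""
        if self.is_empty:
            return np.zeros(len(points), dtype=bool)
        local = (np.asarray(points) - np.asarray(self.center)) @ self.rotation
        scaled = local / np.asarray(self.semi_axes)
        return np.einsum("ij,ij->i", scaled, scaled) <= 1.0


def ellipsoid_semi_axes(volume_ml: float, ratios: tuple) -> tuple:
    """Semi-axes (m) proportional to ``ratios`` enclosing ``volume_ml``.

    Solves (4/3) pi a b c = V with (a, b, c) = s * ratios.  A zero
    volume returns the degenerate (0, 0, 0) empty lesion.
    """
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    rx, ry, rz = ratios
    if min(rx, ry, rz) <= 0:
        raise ValueError("axis ratios must be positive")
    if volume_ml == 0:
        return (0.0, 0.0, 0.0)
    v = volume_ml / ML_PER_M3
    s = (v / ((4.0 / 3.0) * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    return (s * rx, s * ry, s * rz)


def rotation_about_axis(axis: tuple, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    u = np.asarray(axis, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    u = u / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def make_layered_head(layers: HeadLayers = HeadLayers(),
                      spacing: float = 0.002,
                      padding: float = 0.0) -> VoxelPhantom:
    """Voxelize the concentric layered head model.

    The grid covers the head sphere plus ``padding`` on each side.
    ``spacing`` must resolve the thinnest shell (<= skull thickness).
    """
    if spacing > layers.skull_thickness:
        raise ResolutionError(
            f"spacing {spacing} m cannot resolve skull thickness "
            f"{layers.skull_thickness} m")
    half = layers.outer_radius + padding
    n = int(np.ceil(2 * half / spacing))
    center = np.asarray(layers.center, dtype=float)
    origin = center - spacing * n / 2.0
    ax = origin[0] + spacing * (np.arange(n) + 0.5) - center[0]
    ay = origin[1] + spacing * (np.arange(n) + 0.5) - center[1]
    az = origin[2] + spacing * (np.arange(n) + 0.5) - center[2]
    r2 = (ax[:, None, None] ** 2 + ay[None, :, None] ** 2
          + az[None, None, :] ** 2)
    labels = np.zeros((n, n, n), dtype=np.int8)
    labels[r2 <= layers.outer_radius ** 2] = 1
    labels[r2 <= layers.skull_inner ** 2] = 2
    labels[r2 <= layers.csf_inner ** 2] = 3
    labels[r2 <= layers.gray_inner ** 2] = 4
    return VoxelPhantom(spacing=spacing, origin=origin, labels=labels)


def insert_lesion(phantom: VoxelPhantom, lesion: EllipsoidLesion) -> VoxelPhantom:
    """Relabel voxels whose centers fall inside the lesion as blood.

    Returns a new phantom; all other labels are preserved.  Warns if the
    lesion overlaps skull/CSF or exits the phantom grid.  An empty
    lesion returns an identical copy.
    """
    out = phantom.copy()
    out.label_map.setdefault(BLOOD_LABEL, "blood")
    if lesion.is_empty:
        return out
    # restrict work to the lesion's bounding box
    reach = np.linalg.norm(lesion.rotation * np.asarray(lesion.semi_axes), axis=1)
    lo_w = np.asarray(lesion.center) - reach
    hi_w = np.asarray(lesion.center) + reach
    lo = np.maximum(np.floor((lo_w - phantom.origin) / phantom.spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - phantom.origin) / phantom.spacing).astype(int),
                    np.asarray(phantom.shape))
    if np.any(hi <= lo):
        warnings.warn("lesion lies entirely outside the phantom grid")
        return out
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    idx = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    centers = phantom.origin + phantom.spacing * (idx + 0.5)
    inside = lesion.contains(centers).reshape(tuple(h - l for l, h in zip(lo, hi)))
    sub = out.labels[sl]
    covered = {phantom.label_map[l] for l in np.unique(sub[inside])}
    if covered - {"white_matter", "gray_matter", "blood"}:
        warnings.warn(f"lesion overlaps non-brain tissue: {sorted(covered)}")
    sub[inside] = BLOOD_LABEL
    out.labels[sl] = sub
    return out


def measure_lesion_volume(phantom: VoxelPhantom) -> float:
    """Blood voxel count x spacing^3, in ml (0 if no blood present)."""
    blood_labels = [l for l, t in phantom.label_map.items() if t == "blood"]
    if not blood_labels:
        return 0.0
    n = int(np.isin(phantom.labels, blood_labels).sum())
    return n * phantom.spacing ** 3 * ML_PER_M3


def projected_cross_section(lesion: EllipsoidLesion, direction: tuple) -> float:
    """Shadow area (m^2) of the ellipsoid on the plane normal to ``direction``.

    Closed form: with M = R diag(a^2, b^2, c^2) R^T and unit u,
    area = pi sqrt(det(M) u^T M^{-1} u).  For a sphere this is pi r^2
    for any direction.
    """
    if lesion.is_empty:
        raise ValueError("projected cross section of an empty lesion")
    u = np.asarray(direction, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("direction must be a non-zero vector")
    u = u / n
    a2 = np.asarray(lesion.semi_axes, dtype=float) ** 2
    M = lesion.rotation @ np.diag(a2) @ lesion.rotation.T
    det = np.prod(a2)
    return float(np.pi * np.sqrt(det * (u @ np.linalg.solve(M, u))))


# ---------------------------------------------------------------------------
# plain-text save/load (label grid as ASCII, JSON sidecar with geometry)

def save_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Save as a JSON header + flattened ASCII label grid (text format)."""
    path = Path(path)
    header = {
        "spacing": phantom.spacing,
        "origin": phantom.origin.tolist(),
        "shape": list(phantom.shape),
        "label_map": {str(k): v for k, v in phantom.label_map.items()},
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        flat = phantom.labels.reshape(-1)
        for i in range(0, flat.size, 1000):
            fh.write(" ".join(map(str, flat[i:i + 1000])) + "\n")


def load_phantom(path: str | Path) -> VoxelPhantom:
    path = Path(path)
    with path.open() as fh:
        header = json.loads(fh.readline())
        flat = np.array(fh.read().split(), dtype=np.int64)
    labels = flat.reshape(header["shape"]).astype(np.int8)
    return VoxelPhantom(spacing=header["spacing"],
                        origin=np.asarray(header["origin"]),
                        labels=labels,
                        label_map={int(k): v for k, v in header["label_map"].items()})
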