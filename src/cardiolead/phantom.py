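"""Structured heart-torso phantoms on cartesian hexahedral grids.

The phantom emulates the compartments of a torso volume conductor that shape
the surface ECG: a ventricle-like myocardial shell with rotating anisotropic
fibers enclosing a blood cavity, two lungs, a subcutaneous skeletal-muscle
layer, isotropic bulk body, and non-conducting exterior.  Geometry is
deliberately simple (box torso, ellipsoidal organs) but exhibits every
tissue interface that matters for lead-field downsampling: myocardium-blood,
myocardium-lung, muscle-body, and the body surface itself.

Conventions: element (i,j,k) spans nodes (i..i+1, j..j+1, k..k+1); node
(i,j,k) sits at ``origin + spacing*(i,j,k)``; all lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Tissue",
    "ElementMesh",
    "NodeMesh",
    "ElectrodeSet",
    "PhantomConfig",
    "ConfigurationError",
    "PlacementError",
    "build_phantom",
    "derive_node_mesh",
    "place_electrodes",
    "default_electrode_positions",
    "default_stimulus_sites",
    "fiber_variability",
    "fiber_variability_measure",
]


class ConfigurationError(ValueError):
    """Phantom geometry or simulation configuration is inconsistent."""


class PlacementError(ValueError):
    """An electrode request could not be matched to a surface node."""


class Tissue(IntEnum):
    """Tissue compartment labels (EXTERIOR carries zero conductivity)."""

    EXTERIOR = 0
    MYOCARDIUM = 1
    BLOOD = 2
    LUNG = 3
    MUSCLE = 4
    BODY = 5


# Node types derived from the element mesh.
NODE_EXTERIOR = 0
NODE_MYOCARDIAL = 1
NODE_CONDUCTING = 2  # conducting but not myocardial


@dataclass
class ElementMesh:
    """Structured hexahedral grid with per-element tissue and fiber frames.

    ``fiber``/``sheet``/``normal`` form a right-handed orthonormal frame on
    every conducting element: ``fiber`` is the longitudinal axis, ``sheet``
    the within-sheet transverse axis, ``normal`` the across-sheet axis.
    """

    dims: tuple[int, int, int]
    spacing: float  # mm, uniform along all axes
    origin: tuple[float, float, float]
    tissue: np.ndarray  # uint8, shape dims
    fiber: np.ndarray  # float, dims + (3,)
    sheet: np.ndarray
    normal: np.ndarray

    @property
    def node_dims(self) -> tuple[int, int, int]:
        return tuple(d + 1 for d in self.dims)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.node_dims
        return nx * ny * nz

    @property
    def spacing_cm(self) -> float:
        return self.spacing / 10.0

    def element_centers(self) -> np.ndarray:
        """Centers of all elements, shape dims + (3,), in mm."""
        axes = [
            self.origin[a] + self.spacing * (np.arange(self.dims[a]) + 0.5)
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def node_coords(self) -> np.ndarray:
        """Coordinates of all nodes, shape node_dims + (3,), in mm."""
        axes = [
            self.origin[a] + self.spacing * np.arange(self.dims[a] + 1)
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def conducting_mask(self) -> np.ndarray:
        return self.tissue != Tissue.EXTERIOR

    def validate_frames(self, atol: float = 1e-6) -> None:
        """Check orthonormality of fiber frames on conducting elements."""
        mask = self.conducting_mask()
        f, s, n = self.fiber[mask], self.sheet[mask], self.normal[mask]
        for v in (f, s, n):
            if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=atol):
                raise ConfigurationError("fiber frame vectors not unit length")
        if not (
            np.allclose(np.sum(f * s, axis=-1), 0.0, atol=atol)
            and np.allclose(np.sum(f * n, axis=-1), 0.0, atol=atol)
            and np.allclose(np.sum(s * n, axis=-1), 0.0, atol=atol)
        ):
            raise ConfigurationError("fiber frame vectors not orthogonal")


@dataclass
class NodeMesh:
    """Node typing and per-node surface-to-volume ratio derived from elements.

    ``beta_node`` is the average of the per-element beta over the 8 incident
    elements (zero contribution from non-myocardium and from slots outside
    the grid), so a node is myocardial exactly when ``beta_node > 0``.
    """

    dims: tuple[int, int, int]
    node_type: np.ndarray  # uint8, shape dims
    beta_node: np.ndarray  # cm^-1, shape dims

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def myocardial_mask(self) -> np.ndarray:
        return self.node_type == NODE_MYOCARDIAL

    def conducting_flat(self) -> np.ndarray:
        return (self.node_type != NODE_EXTERIOR).ravel()


@dataclass
class ElectrodeSet:
    """Named electrodes snapped to surface nodes of an ElementMesh."""

    names: list[str]
    node_ijk: np.ndarray  # (n, 3) int
    mesh: ElementMesh

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise PlacementError("duplicate electrode name")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def flat_node(self, name: str) -> int:
        i, j, k = self.node_ijk[self.index(name)]
        nx, ny, nz = self.mesh.node_dims
        return int((i * ny + j) * nz + k)

    def positions_mm(self) -> np.ndarray:
        return np.asarray(self.mesh.origin) + self.mesh.spacing * self.node_ijk


def default_electrode_positions(config: "PhantomConfig") -> dict[str, tuple]:
    """Standard 9-electrode layout (limbs + V1-V6) on the box torso surface.

    The x axis is patient right-to-left, y posterior-to-anterior, z
    caudo-cranial.  Arm electrodes sit high on the lateral faces, hip
    electrodes low; the precordials run across the anterior face at heart
    level.
    """
    ext = np.asarray(config.n_elements) * config.spacing_mm
    m = config.exterior_margin * config.spacing_mm
    xlo, xhi = m, ext[0] - m
    yhi = ext[1] - m
    cz = config.heart_center_mm[2]
    ztop, zbot = ext[2] - 5 * config.spacing_mm, m + 2 * config.spacing_mm
    ymid = ext[1] / 2
    return {
        "RA": (xlo, ymid, ztop),
        "LA": (xhi, ymid, ztop),
        "RL": (xlo, ymid, zbot),
        "LL": (xhi, ymid, zbot),
        "V1": (ext[0] * 0.40, yhi, cz + 2 * config.spacing_mm),
        "V2": (ext[0] * 0.50, yhi, cz + 2 * config.spacing_mm),
        "V3": (ext[0] * 0.58, yhi, cz),
        "V4": (ext[0] * 0.66, yhi, cz - 2 * config.spacing_mm),
        "V5": (ext[0] * 0.76, yhi, cz - 2 * config.spacing_mm),
        "V6": (ext[0] * 0.86, yhi, cz - 2 * config.spacing_mm),
    }


@dataclass
class PhantomConfig:
    """Parameters of the synthetic heart-torso phantom.

    Defaults describe the standard study phantom: an 8 cm box torso at 2 mm
    spacing (40^3 elements) with a 10 mm subcutaneous muscle layer, two
    lungs flanking (and abutting) a truncated-ellipsoid myocardial shell
    whose fibers rotate linearly from -60 deg (endo) to +60 deg (epi).
    """

    n_elements: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: float = 2.0
    coarse_ratio: int = 2
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    exterior_margin: int = 1  # elements of EXTERIOR on every face
    muscle_thickness_mm: float = 10.0
    heart_center_mm: tuple[float, float, float] = (40.0, 44.0, 40.0)
    heart_outer_semi_mm: tuple[float, float, float] = (16.0, 16.0, 20.0)
    wall_thickness_mm: float = 8.0
    base_fraction: float = 0.5  # shell truncated at cz + c*base_fraction
    lung_centers_mm: tuple = ((22.0, 40.0, 46.0), (58.0, 40.0, 46.0))
    lung_semi_mm: tuple = ((12.0, 12.0, 20.0), (12.0, 12.0, 20.0))
    fiber_angles_deg: tuple[float, float] = (-60.0, 60.0)  # endo, epi
    electrodes: dict | None = None  # name -> xyz mm; None = standard layout
    seed: int = 0

    def __post_init__(self):
        if int(self.coarse_ratio) != self.coarse_ratio or self.coarse_ratio < 1:
            raise ConfigurationError("coarse_ratio must be an integer >= 1")
        self.coarse_ratio = int(self.coarse_ratio)
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing must be positive")
        if self.exterior_margin < 1:
            raise ConfigurationError("need >= 1 element of exterior margin")

    @property
    def coarse_spacing_mm(self) -> float:
        return self.spacing_mm * self.coarse_ratio

    def scaled(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


def _identity_frames(dims) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f = np.zeros(dims + (3,))
    s = np.zeros(dims + (3,))
    n = np.zeros(dims + (3,))
    f[..., 0] = 1.0
    s[..., 1] = 1.0
    n[..., 2] = 1.0
    return f, s, n


def _normalize(v: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    nrm = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = nrm[..., 0] < 1e-12
    out = np.where(bad[..., None], 1.0 if fallback is None else fallback, v)
    nrm = np.linalg.norm(out, axis=-1, keepdims=True)
    return out / nrm


def build_phantom(config: PhantomConfig) -> ElementMesh:
    """Build the tissue label field and fiber frames for a phantom.

    Deterministic for a fixed config (the geometry is rule-based; ``seed``
    is recorded for provenance and reserved for future stochastic options).

    Raises
    ------
    ConfigurationError
        If the heart shell clips the muscle layer or comes within two
        elements of the exterior boundary.
    """
    dims = tuple(int(d) for d in config.n_elements)
    h = config.spacing_mm
    tissue = np.full(dims, int(Tissue.EXTERIOR), dtype=np.uint8)
    centers = ElementMesh(
        dims, h, tuple(config.origin_mm),
        tissue, *_identity_frames(dims)
    ).element_centers()
    x, y, z = centers[..., 0], centers[..., 1], centers[..., 2]

    # --- body box -----------------------------------------------------
    m = config.exterior_margin
    body = np.zeros(dims, dtype=bool)
    body[m:dims[0] - m, m:dims[1] - m, m:dims[2] - m] = True
    tissue[body] = Tissue.BODY

    # --- subcutaneous muscle layer on the lateral (x, y) faces --------
    ox, oy, _ = config.origin_mm
    xmin, xmax = ox + m * h, ox + (dims[0] - m) * h
    ymin, ymax = oy + m * h, oy + (dims[1] - m) * h
    dists = np.stack([x - xmin, xmax - x, y - ymin, ymax - y], axis=-1)
    lateral = np.min(dists, axis=-1)
    muscle = body & (lateral < config.muscle_thickness_mm)
    tissue[muscle] = Tissue.MUSCLE
    # outward surface normal axis: nearest face, ties broken by order
    face_axis = np.argmin(dists, axis=-1)  # 0:-x 1:+x 2:-y 3:+y

    # --- lungs (only where currently bulk body) -----------------------
    for ctr, semi in zip(config.lung_centers_mm, config.lung_semi_mm):
        rho2 = (
            ((x - ctr[0]) / semi[0]) ** 2
            + ((y - ctr[1]) / semi[1]) ** 2
            + ((z - ctr[2]) / semi[2]) ** 2
        )
        tissue[(rho2 <= 1.0) & (tissue == Tissue.BODY)] = Tissue.LUNG

    # --- heart: truncated ellipsoidal shell closed by a basal cap -----
    cx, cy, cz = config.heart_center_mm
    a, b, c = config.heart_outer_semi_mm
    w = config.wall_thickness_mm
    ai, bi, ci = a - w, b - w, c - w
    if min(ai, bi, ci) <= 0:
        raise ConfigurationError("wall thickness exceeds heart semi-axes")
    dx, dy, dz = x - cx, y - cy, z - cz
    m_out = np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)
    m_in = np.sqrt((dx / ai) ** 2 + (dy / bi) ** 2 + (dz / ci) ** 2)
    z_base = cz + c * config.base_fraction
    in_outer = m_out <= 1.0
    in_inner = m_in <= 1.0
    below_base = z <= z_base
    shell = in_outer & ~in_inner & below_base
    cap = in_inner & below_base & (z > z_base - w)
    myo = shell | cap
    blood = in_inner & (z <= z_base - w)

    heart = myo | blood
    if np.any(heart & (tissue == Tissue.MUSCLE)):
        raise ConfigurationError("heart shell clips the muscle layer")
    # margin >= 2 elements from the exterior along every axis
    grown = heart.copy()
    for axis in range(3):
        for shift in (-2, -1, 1, 2):
            grown |= np.roll(heart, shift, axis=axis)
    if np.any(grown & (tissue == Tissue.EXTERIOR)):
        raise ConfigurationError("heart shell too close to the torso boundary")
    tissue[myo] = Tissue.MYOCARDIUM
    tissue[blood] = Tissue.BLOOD

    # --- fiber frames -------------------------------------------------
    fiber, sheet, normal = _identity_frames(dims)

    # muscle: across-sheet axis = outward surface normal; in-plane isotropic
    ax_vec = np.zeros(dims + (3,))
    sgn = np.where((face_axis % 2) == 0, -1.0, 1.0)
    ax_idx = face_axis // 2  # 0 -> x face, 1 -> y face
    for aidx in (0, 1):
        sel = muscle & (ax_idx == aidx)
        ax_vec[sel, aidx] = sgn[sel]
    tang1 = np.zeros(dims + (3,))
    tang2 = np.zeros(dims + (3,))
    selx = muscle & (ax_idx == 0)
    tang1[selx, 1] = 1.0
    tang2[selx] = np.cross(ax_vec[selx], tang1[selx])
    sely = muscle & (ax_idx == 1)
    tang1[sely, 0] = 1.0
    tang2[sely] = np.cross(ax_vec[sely], tang1[sely])
    fiber[muscle] = tang1[muscle]
    sheet[muscle] = tang2[muscle]
    normal[muscle] = ax_vec[muscle]

    # myocardium: linear transmural rotation in the shell's tangent plane
    rad = np.stack([dx / a**2, dy / b**2, dz / c**2], axis=-1)
    rhat = _normalize(rad, fallback=np.array([0.0, 0.0, 1.0]))
    zhat = np.zeros_like(rhat)
    zhat[..., 2] = 1.0
    e_c = np.cross(zhat, rhat)
    deg = np.linalg.norm(e_c, axis=-1) < 1e-6
    if np.any(deg):
        xhat = np.zeros_like(rhat)
        xhat[..., 0] = 1.0
        e_c[deg] = np.cross(xhat, rhat)[deg]
    e_c = _normalize(e_c)
    e_l = _normalize(np.cross(rhat, e_c))
    wall_out = np.maximum(1.0 - m_out, 0.0)
    wall_in = np.maximum(m_in - 1.0, 0.0)
    with np.errstate(invalid="ignore"):
        t_epi = np.where(wall_out + wall_in > 0, wall_in / (wall_out + wall_in), 0.5)
    a_endo, a_epi = np.deg2rad(config.fiber_angles_deg[0]), np.deg2rad(
        config.fiber_angles_deg[1]
    )
    alpha = a_endo * (1.0 - t_epi) + a_epi * t_epi
    f_myo = (
        np.cos(alpha)[..., None] * e_c + np.sin(alpha)[..., None] * e_l
    )
    f_myo = _normalize(f_myo)
    s_myo = _normalize(np.cross(rhat, f_myo))
    n_myo = np.cross(f_myo, s_myo)
    fiber[myo] = f_myo[myo]
    sheet[myo] = s_myo[myo]
    normal[myo] = n_myo[myo]

    mesh = ElementMesh(
        dims=dims,
        spacing=h,
        origin=tuple(config.origin_mm),
        tissue=tissue,
        fiber=fiber,
        sheet=sheet,
        normal=normal,
    )
    mesh.validate_frames()
    for t in (Tissue.MYOCARDIUM, Tissue.BLOOD, Tissue.LUNG, Tissue.MUSCLE,
              Tissue.BODY, Tissue.EXTERIOR):
        if not np.any(tissue == t):
            raise ConfigurationError(f"phantom missing tissue {t.name}")
    return mesh


def _node_sum(elem: np.ndarray) -> np.ndarray:
    """Sum an element quantity over the 8 elements incident to each node."""
    p = np.pad(elem, 1)
    return (
        p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, 1:, :-1] + p[:-1, :-1, 1:]
        + p[1:, 1:, :-1] + p[1:, :-1, 1:] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]
    )


def derive_node_mesh(mesh: ElementMesh, beta_myo: float = 800.0) -> NodeMesh:
    """Derive node types and nodal beta from the element mesh.

    Every corner node of a myocardial element is myocardial; ``beta_node``
    is the 8-element incident average of the per-element beta (zero for
    non-myocardium), so boundary nodes carry proportionally less membrane.
    """
    myo_e = (mesh.tissue == Tissue.MYOCARDIUM).astype(float)
    cond_e = mesh.conducting_mask().astype(float)
    beta = _node_sum(myo_e * beta_myo) / 8.0
    node_type = np.full(mesh.node_dims, NODE_EXTERIOR, dtype=np.uint8)
    node_type[_node_sum(cond_e) > 0] = NODE_CONDUCTING
    node_type[_node_sum(myo_e) > 0] = NODE_MYOCARDIAL
    return NodeMesh(dims=mesh.node_dims, node_type=node_type, beta_node=beta)


def surface_node_mask(mesh: ElementMesh) -> np.ndarray:
    """Conducting nodes with at least one exterior (or out-of-grid) incident
    element slot."""
    cond_e = mesh.conducting_mask().astype(float)
    n_cond = _node_sum(cond_e)
    return (n_cond > 0) & (n_cond < 8)


def place_electrodes(
    mesh: ElementMesh,
    spec: dict[str, tuple],
    tolerance_mm: float | None = None,
) -> ElectrodeSet:
    """Snap requested electrode positions to the nearest surface nodes.

    Parameters
    ----------
    spec : mapping name -> (x, y, z) in mm.
    tolerance_mm : maximum allowed snap distance (default 3 x spacing).
    """
    if tolerance_mm is None:
        tolerance_mm = 3.0 * mesh.spacing
    names = list(spec)
    if len(set(names)) != len(names):
        raise PlacementError("duplicate electrode name")
    surf = surface_node_mask(mesh)
    surf_ijk = np.argwhere(surf)
    if surf_ijk.size == 0:
        raise PlacementError("mesh has no surface nodes")
    surf_xyz = np.asarray(mesh.origin) + mesh.spacing * surf_ijk
    node_ijk = np.zeros((len(names), 3), dtype=int)
    for row, name in enumerate(names):
        p = np.asarray(spec[name], dtype=float)
        d = np.linalg.norm(surf_xyz - p, axis=1)
        best = int(np.argmin(d))
        if d[best] > tolerance_mm:
            raise PlacementError(
                f"electrode {name!r} is {d[best]:.1f} mm from the nearest "
                f"surface node (tolerance {tolerance_mm:.1f} mm)"
            )
        node_ijk[row] = surf_ijk[best]
    return ElectrodeSet(names=names, node_ijk=node_ijk, mesh=mesh)


def default_stimulus_sites(config: PhantomConfig) -> list[tuple[float, float, float]]:
    """Seven stimulus sites spread over the myocardial shell.

    Mid-wall positions: six around the equator-to-apex band at distinct
    azimuths plus one at the apex, emulating distinct activation origins.
    """
    cx, cy, cz = config.heart_center_mm
    a, b, c = config.heart_outer_semi_mm
    w = config.wall_thickness_mm
    fm = 1.0 - 0.5 * w / min(a, b, c)  # mid-wall scale factor
    sites = []
    for i, (az, pol) in enumerate(
        [(0, 90), (60, 90), (120, 110), (180, 90), (240, 110), (300, 90)]
    ):
        th, ph = np.deg2rad(pol), np.deg2rad(az)
        sites.append((
            cx + fm * a * np.sin(th) * np.cos(ph),
            cy + fm * b * np.sin(th) * np.sin(ph),
            cz + fm * c * np.cos(th),
        ))
    sites.append((cx, cy, cz - fm * c))  # apex
    return sites


def fiber_variability_measure(P: np.ndarray, fibers: np.ndarray) -> float:
    """Variability of fine fibers ``p_i`` against a coarse direction ``P``:
    ``1 - (1/N) * sum_i |P . p_i|`` (orientation, not direction, matters)."""
    P = np.asarray(P, dtype=float)
    P = P / np.linalg.norm(P)
    fibers = np.asarray(fibers, dtype=float)
    if fibers.ndim == 1:
        fibers = fibers[None, :]
    return float(1.0 - np.mean(np.abs(fibers @ P)))


def fiber_variability(
    fine: ElementMesh, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coarse-block fiber-direction variability of the fine mesh.

    For each block of ``n^3`` fine elements containing myocardium, the
    coarse direction P is the principal eigenvector of the block's fiber
    orientation tensor (the sign-invariant realization of a block-averaged,
    renormalized direction) and the value is
    ``1 - mean_i |P . p_i|`` over the myocardial fine fibers.

    Returns ``(values, valid)``; blocks without myocardium are flagged
    invalid and carry NaN, never zero.
    """
    if n < 1:
        raise ValueError("block factor must be >= 1")
    dims = fine.dims
    bdims = tuple(-(-d // n) for d in dims)
    values = np.full(bdims, np.nan)
    valid = np.zeros(bdims, dtype=bool)
    myo = fine.tissue == Tissue.MYOCARDIUM
    for bi in range(bdims[0]):
        for bj in range(bdims[1]):
            for bk in range(bdims[2]):
                sl = np.s_[
                    bi * n : (bi + 1) * n,
                    bj * n : (bj + 1) * n,
                    bk * n : (bk + 1) * n,
                ]
                sel = myo[sl]
                if not np.any(sel):
                    continue
                p = fine.fiber[sl][sel]
                tensor = p.T @ p / len(p)
                _, vecs = np.linalg.eigh(tensor)
                P = vecs[:, -1]
                values[bi, bj, bk] = 1.0 - np.mean(np.abs(p @ P))
                valid[bi, bj, bk] = True
    return values, valid
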