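"""Ready-made phantoms, strands and synthetic Vm movies for tests and demos.

``make_fixture`` builds phantoms at three scales — ``tiny`` (10^3 elements,
sub-second, for unit tests), ``small`` (20^3, for solver and reciprocity
checks) and ``default`` (the 40^3 study phantom).  ``planar_wave_series``
produces a travelling depolarization front as a canned Vm movie, so ECG
machinery can be exercised without running the monodomain model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .monodomain import VmSeries
from .phantom import (
    ElementMesh,
    ElectrodeSet,
    NodeMesh,
    PhantomConfig,
    Tissue,
    build_phantom,
    default_electrode_positions,
    derive_node_mesh,
    place_electrodes,
)

__all__ = [
    "Fixture",
    "make_fixture",
    "strand_mesh",
    "planar_wave_series",
    "TINY_CONFIG",
    "SMALL_CONFIG",
    "DEFAULT_CONFIG",
]


DEFAULT_CONFIG = PhantomConfig()

SMALL_CONFIG = PhantomConfig(
    n_elements=(20, 20, 20),
    spacing_mm=4.0,
    coarse_ratio=2,
    muscle_thickness_mm=8.0,
    heart_center_mm=(40.0, 44.0, 40.0),
    heart_outer_semi_mm=(16.0, 16.0, 20.0),
    wall_thickness_mm=8.0,
    lung_centers_mm=((22.0, 40.0, 46.0), (58.0, 40.0, 46.0)),
    lung_semi_mm=((12.0, 12.0, 20.0), (12.0, 12.0, 20.0)),
)

TINY_CONFIG = PhantomConfig(
    n_elements=(10, 10, 10),
    spacing_mm=8.0,
    coarse_ratio=2,
    muscle_thickness_mm=8.0,
    heart_center_mm=(40.0, 44.0, 40.0),
    heart_outer_semi_mm=(16.0, 16.0, 20.0),
    wall_thickness_mm=8.0,
    lung_centers_mm=((22.0, 40.0, 46.0), (58.0, 40.0, 46.0)),
    lung_semi_mm=((12.0, 12.0, 20.0), (12.0, 12.0, 20.0)),
)


@dataclass
class Fixture:
    config: PhantomConfig
    mesh: ElementMesh
    nodes: NodeMesh
    electrodes: ElectrodeSet


def make_fixture(size: str = "tiny", seed: int = 0) -> Fixture:
    """Deterministic phantom fixture at one of three scales."""
    cfg = {"tiny": TINY_CONFIG, "small": SMALL_CONFIG, "default": DEFAULT_CONFIG}[
        size
    ]
    cfg = replace(cfg, seed=seed)
    mesh = build_phantom(cfg)
    nodes = derive_node_mesh(mesh)
    positions = cfg.electrodes or default_electrode_positions(cfg)
    electrodes = place_electrodes(mesh, positions)
    return Fixture(config=cfg, mesh=mesh, nodes=nodes, electrodes=electrodes)


def homogeneous_box(
    n: int = 64, spacing_mm: float = 2.0, margin: int = 1
) -> ElementMesh:
    """Isotropic all-body box (exterior margin) for analytic point-source
    comparisons; the fiber frame is the identity everywhere."""
    dims = (n, n, n)
    tissue = np.full(dims, int(Tissue.EXTERIOR), dtype=np.uint8)
    tissue[margin:-margin, margin:-margin, margin:-margin] = Tissue.BODY
    fiber = np.zeros(dims + (3,))
    sheet = np.zeros(dims + (3,))
    normal = np.zeros(dims + (3,))
    fiber[..., 0] = 1.0
    sheet[..., 1] = 1.0
    normal[..., 2] = 1.0
    return ElementMesh(
        dims=dims, spacing=spacing_mm, origin=(0.0, 0.0, 0.0),
        tissue=tissue, fiber=fiber, sheet=sheet, normal=normal,
    )


def strand_mesh(
    n_long: int = 150,
    cross: int = 2,
    spacing_mm: float = 0.2,
    margin: int = 1,
) -> ElementMesh:
    """Myocardial strand along x with fibers x-aligned, exterior all around.

    The classic 1-D cable setup for conduction-velocity measurements; the
    2x2-element cross-section gives the center node line the full nodal
    surface-to-volume ratio.
    """
    dims = (n_long + 2 * margin, cross + 2 * margin, cross + 2 * margin)
    tissue = np.full(dims, int(Tissue.EXTERIOR), dtype=np.uint8)
    tissue[margin:-margin, margin:-margin, margin:-margin] = Tissue.MYOCARDIUM
    fiber = np.zeros(dims + (3,))
    sheet = np.zeros(dims + (3,))
    normal = np.zeros(dims + (3,))
    fiber[..., 0] = 1.0
    sheet[..., 1] = 1.0
    normal[..., 2] = 1.0
    return ElementMesh(
        dims=dims,
        spacing=spacing_mm,
        origin=(0.0, 0.0, 0.0),
        tissue=tissue,
        fiber=fiber,
        sheet=sheet,
        normal=normal,
    )


def planar_wave_series(
    mesh: ElementMesh,
    nodes: NodeMesh,
    direction=(1.0, 0.0, 0.0),
    speed_mm_ms: float = 0.5,
    front_width_mm: float = 4.0,
    duration_ms: float = 100.0,
    sample_interval_ms: float = 1.0,
    rest_Vm: float = -80.0,
    amplitude: float = 100.0,
    seed: int = 0,
) -> VmSeries:
    """Synthetic Vm movie: a sigmoidal depolarization front sweeping the
    myocardium along ``direction`` at constant speed.  Purely kinematic —
    no reaction-diffusion dynamics — but with physiologic amplitudes, so
    ECG evaluators see realistic gradients."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    myo_flat = np.flatnonzero(nodes.myocardial_mask().ravel())
    ijk = np.stack(np.unravel_index(myo_flat, nodes.dims), axis=-1)
    xyz = np.asarray(mesh.origin) + mesh.spacing * ijk
    s = xyz @ d
    s = s - s.min()
    n_frames = int(round(duration_ms / sample_interval_ms)) + 1
    times = np.arange(n_frames) * sample_interval_ms
    frames = np.empty((n_frames, myo_flat.size))
    for i, t in enumerate(times):
        phase = (speed_mm_ms * t - s) / front_width_mm
        frames[i] = rest_Vm + amplitude / (1.0 + np.exp(-4.0 * phase))
    return VmSeries(
        frames=frames,
        sample_interval_ms=sample_interval_ms,
        myo_flat=myo_flat,
        rest_Vm=rest_Vm,
        mesh=mesh,
        nodes=nodes,
        config_hash="planar-wave",
        seed=seed,
    )
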