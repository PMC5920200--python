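"""HDF5/JSON/CSV containers for meshes, Vm series, lead fields, electrodes.

Array datasets are stored in z-y-x order (transposed on write and read), a
convention shared with common volume-imaging formats; lengths are mm.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .leadfield import GradLeadField, Lead, LeadField
from .monodomain import VmSeries
from .phantom import ElementMesh, ElectrodeSet, NodeMesh, Tissue, derive_node_mesh

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_vm_series",
    "load_vm_series",
    "save_lead_fields",
    "load_lead_fields",
    "save_electrodes",
    "load_electrodes",
    "save_grad_fields",
    "load_grad_fields",
]

_TISSUE_CODES = {t.name: int(t) for t in Tissue}


def _zyx(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.swapaxes(a, 0, 2))


def save_mesh(path, mesh: ElementMesh) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tissue", data=_zyx(mesh.tissue), dtype="uint8")
        for name in ("fiber", "sheet", "normal"):
            arr = getattr(mesh, name)
            f.create_dataset(name, data=np.swapaxes(arr, 0, 2), dtype="f4")
        f.attrs["dims"] = mesh.dims
        f.attrs["spacing_mm"] = mesh.spacing
        f.attrs["origin_mm"] = mesh.origin
        f.attrs["tissue_codes"] = json.dumps(_TISSUE_CODES)


def load_mesh(path) -> ElementMesh:
    with h5py.File(path, "r") as f:
        dims = tuple(int(d) for d in f.attrs["dims"])
        mesh = ElementMesh(
            dims=dims,
            spacing=float(f.attrs["spacing_mm"]),
            origin=tuple(float(v) for v in f.attrs["origin_mm"]),
            tissue=_zyx(f["tissue"][()]),
            fiber=np.swapaxes(f["fiber"][()], 0, 2).astype(float),
            sheet=np.swapaxes(f["sheet"][()], 0, 2).astype(float),
            normal=np.swapaxes(f["normal"][()], 0, 2).astype(float),
        )
    return mesh


def save_vm_series(path, series: VmSeries) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("vm")
        for i in range(series.n_frames):
            g.create_dataset(f"frame_{i:06d}", data=series.frames[i], dtype="f4")
        g.create_dataset("times_ms", data=series.times_ms)
        g.create_dataset("myo_flat", data=series.myo_flat)
        g.attrs["sample_interval_ms"] = series.sample_interval_ms
        g.attrs["rest_Vm"] = series.rest_Vm
        g.attrs["config_hash"] = series.config_hash
        g.attrs["seed"] = series.seed


def load_vm_series(path, mesh: ElementMesh, nodes: NodeMesh | None = None) -> VmSeries:
    nodes = nodes if nodes is not None else derive_node_mesh(mesh)
    with h5py.File(path, "r") as f:
        g = f["vm"]
        names = sorted(k for k in g.keys() if k.startswith("frame_"))
        frames = np.stack([g[k][()].astype(float) for k in names])
        return VmSeries(
            frames=frames,
            sample_interval_ms=float(g.attrs["sample_interval_ms"]),
            myo_flat=g["myo_flat"][()],
            rest_Vm=float(g.attrs["rest_Vm"]),
            mesh=mesh,
            nodes=nodes,
            config_hash=str(g.attrs.get("config_hash", "")),
            seed=int(g.attrs.get("seed", 0)),
        )


def save_electrodes(path, es: ElectrodeSet) -> None:
    data = [
        {"name": n, "node_ijk": [int(v) for v in es.node_ijk[i]],
         "xyz_mm": [float(v) for v in es.positions_mm()[i]]}
        for i, n in enumerate(es.names)
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_electrodes(path, mesh: ElementMesh) -> ElectrodeSet:
    """Read electrodes from JSON; entries carry ``node_ijk`` or, failing
    that, ``xyz_mm`` positions that are snapped to the surface."""
    from .phantom import place_electrodes

    with open(path) as fh:
        data = json.load(fh)
    names = [d["name"] for d in data]
    if all("node_ijk" in d for d in data):
        ijk = np.array([d["node_ijk"] for d in data], dtype=int)
        return ElectrodeSet(names=names, node_ijk=ijk, mesh=mesh)
    return place_electrodes(mesh, {d["name"]: tuple(d["xyz_mm"]) for d in data})


def save_membrane_state(path, state, mode: str = "a") -> None:
    """Checkpoint a MembraneState under /membrane (Vm, gates, other)."""
    with h5py.File(path, mode) as f:
        if "membrane" in f:
            del f["membrane"]
        g = f.create_group("membrane")
        g.create_dataset("Vm", data=state.Vm)
        g.create_dataset("gates", data=state.gates)
        g.create_dataset("other", data=state.other)


def load_membrane_state(path):
    from .membrane import MembraneState

    with h5py.File(path, "r") as f:
        g = f["membrane"]
        return MembraneState(
            Vm=g["Vm"][()], gates=g["gates"][()], other=g["other"][()]
        )


def _lead_to_json(lead: Lead) -> dict:
    return {
        "name": lead.name,
        "terms": [[n, str(c)] for n, c in lead.terms],
    }


def _lead_from_json(d: dict) -> Lead:
    from fractions import Fraction

    return Lead(d["name"], tuple((n, Fraction(c)) for n, c in d["terms"]))


def save_lead_fields(path, fields: list[LeadField]) -> None:
    with h5py.File(path, "w") as f:
        for lf in fields:
            g = f.create_group(f"Z/{lf.lead.name}")
            g.create_dataset("values", data=lf.values)
            g.attrs["lead"] = json.dumps(_lead_to_json(lf.lead))
            g.attrs["tolerance"] = lf.tolerance
            g.attrs["resolution"] = lf.resolution


def load_lead_fields(path, mesh: ElementMesh) -> list[LeadField]:
    out = []
    with h5py.File(path, "r") as f:
        for name in f["Z"]:
            g = f[f"Z/{name}"]
            out.append(
                LeadField(
                    values=g["values"][()],
                    lead=_lead_from_json(json.loads(g.attrs["lead"])),
                    mesh=mesh,
                    tolerance=float(g.attrs["tolerance"]),
                    resolution=str(g.attrs["resolution"]),
                )
            )
    return out


def save_grad_fields(path, grads: list[GradLeadField]) -> None:
    with h5py.File(path, "w") as f:
        for g_ in grads:
            grp = f.create_group(f"gradZ/{g_.lead.name}")
            grp.create_dataset("vectors", data=g_.vectors, dtype="f8")
            if g_.myo_block is not None:
                grp.create_dataset("myo_block", data=g_.myo_block)
            grp.attrs["block"] = g_.block
            grp.attrs["method"] = g_.method
            grp.attrs["fine_dims"] = g_.fine_dims
            grp.attrs["lead"] = json.dumps(_lead_to_json(g_.lead))


def load_grad_fields(path) -> list[GradLeadField]:
    out = []
    with h5py.File(path, "r") as f:
        for name in f["gradZ"]:
            grp = f[f"gradZ/{name}"]
            out.append(
                GradLeadField(
                    vectors=grp["vectors"][()],
                    block=int(grp.attrs["block"]),
                    method=str(grp.attrs["method"]),
                    lead=_lead_from_json(json.loads(grp.attrs["lead"])),
                    fine_dims=tuple(int(d) for d in grp.attrs["fine_dims"]),
                    myo_block=grp["myo_block"][()] if "myo_block" in grp else None,
                )
            )
    return out
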