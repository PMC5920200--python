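"""Extracellular potential solves: fine full solution and coarse projection.

The extracellular field obeys ``div((G_i+G_e) grad phi_e) = -div(G_i grad
Vm)`` with no-flux boundaries, a singular (pure-Neumann) system whose right
side integrates to zero.  The fine-mesh full solution (FSF) solves it on
the simulation grid; the coarse variant (FSC) first projects the nodal
source currents onto a nested coarser grid with trilinear partition-of-
unity weights, which conserves total current exactly, and solves there.

Solves honor a relative-residual contract (default 1e-8): sparse LU for
small systems, preconditioned CG (MINRES fallback) with warm starts for
large ones; the constant mode is projected out and solutions are returned
zero-mean over conducting nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import DiscreteOperator
from .phantom import ElementMesh, ElectrodeSet, NodeMesh, Tissue

__all__ = [
    "SolverError",
    "SourceField",
    "PotentialField",
    "EllipticSolver",
    "build_rhs",
    "project_to_coarse",
    "solve_extracellular",
    "sample_lead_voltage",
    "coarsen_mesh",
    "electrodes_on_coarse",
]


class SolverError(RuntimeError):
    pass


@dataclass
class SourceField:
    """Nodal current sources (uA) for the extracellular solve.

    Values are the assembled right-hand side ``-op_Gi . Vm``; they sum to
    zero (Neumann compatibility) up to rounding.
    """

    values: np.ndarray  # flat, one per node
    mesh: ElementMesh
    resolution: str = "fine"

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class PotentialField:
    """Nodal extracellular potential (mV), zero-mean over conducting nodes
    when ``normalized``."""

    values: np.ndarray
    mesh: ElementMesh
    nodes: NodeMesh
    normalized: bool = True


class EllipticSolver:
    """Reusable solver for one symmetric singular Neumann operator.

    Restricts to the active node set, pins the constant mode, and verifies
    the relative residual after every solve.  Small systems are factorized
    once (SuperLU) and reused; large ones use Jacobi-preconditioned CG with
    warm starts, falling back to MINRES if CG stalls.
    """

    DIRECT_LIMIT = 35_000

    def __init__(self, op: DiscreteOperator, tol: float = 1e-8,
                 method: str = "auto"):
        self.op = op
        self.tol = tol
        self.active = op.active_mask()
        n_active = int(self.active.sum())
        if n_active == 0:
            raise SolverError("operator has no active nodes")
        idx = np.flatnonzero(self.active)
        self.idx = idx
        A = op.matrix.tocsr()[idx][:, idx].tocsr()
        self.A = -A  # negate: div(G grad .) is negative semidefinite
        if method == "auto":
            method = "direct" if n_active <= self.DIRECT_LIMIT else "cg"
        self.method = method
        self._lu = None
        self._x_prev: np.ndarray | None = None
        self._x_prev2: np.ndarray | None = None
        self.last_iterations = 0
        if method == "direct":
            Ap = self.A.tolil()
            Ap[0, :] = 0.0
            Ap[:, 0] = 0.0
            Ap[0, 0] = 1.0
            self._lu = spla.splu(Ap.tocsc())
        else:
            d = self.A.diagonal()
            d = np.where(d > 0, d, 1.0)
            self._Minv = sp.diags(1.0 / d)

    def solve(self, b_full: np.ndarray, warm_start: bool = True) -> np.ndarray:
        """Solve A x = b for a compatible rhs; returns a full-grid field
        (zeros on inactive nodes), not yet normalized."""
        b = -np.asarray(b_full, dtype=float)[self.idx]
        nb = np.linalg.norm(b)
        out = np.zeros(self.op.n_nodes)
        if nb == 0:
            return out
        b = b - b.mean()  # project out the incompatible constant component
        if self._lu is not None:
            bp = b.copy()
            bp[0] = 0.0
            x = self._lu.solve(bp)
            x = x - x.mean()
            self.last_iterations = 1
        else:
            x0 = None
            if warm_start and self._x_prev is not None:
                # linear extrapolation from the two previous solves: sources
                # evolve smoothly between output frames
                if self._x_prev2 is not None:
                    x0 = 2.0 * self._x_prev - self._x_prev2
                else:
                    x0 = self._x_prev
            it = [0]

            def cb(_):
                it[0] += 1

            x, info = spla.cg(
                self.A, b, x0=x0, rtol=self.tol / 2.0, atol=0.0,
                maxiter=20_000, M=self._Minv, callback=cb,
            )
            self.last_iterations = it[0]
            if info != 0 or not self._check(x, b):
                x, info = spla.minres(
                    self.A, b, x0=x, rtol=self.tol / 10.0,
                    maxiter=20_000, M=self._Minv,
                )
            x = x - x.mean()
            self._x_prev2 = self._x_prev
            self._x_prev = x
        r = np.linalg.norm(self.A @ x - b)
        if r > self.tol * nb:
            raise SolverError(
                f"relative residual {r / nb:.2e} exceeds tolerance {self.tol:.0e}"
            )
        out[self.idx] = x
        return out

    def _check(self, x, b) -> bool:
        return np.linalg.norm(self.A @ x - b) <= self.tol * np.linalg.norm(b)


def build_rhs(op_Gi: DiscreteOperator, Vm: np.ndarray) -> SourceField:
    """Right-hand side ``-op_Gi . Vm`` of the extracellular system.

    Uses the myocardium-restricted symmetric form of the intracellular
    operator: Vm is only defined inside the heart, and the no-flux closure
    (couplings to outside nodes lumped onto the diagonal) realizes the
    intracellular boundary condition — it also keeps the discrete sources
    consistent with the element-quadrature lead-field ECG, which never
    references Vm outside the myocardium either.  Nonzero on myocardial
    nodes only; the total vanishes because the symmetric operator
    annihilates constants in rows and columns alike.
    """
    Vm = np.asarray(Vm, dtype=float)
    if Vm.shape != (op_Gi.n_nodes,):
        raise ValueError("Vm does not match the operator's node grid")
    values = -(op_Gi.myocardial_form() @ Vm)
    # rounding floor: row sums of the assembled matrix are zero only to
    # machine precision, and a frame at rest produces pure rounding noise
    scaleA = np.abs(op_Gi.matrix.data).max() if op_Gi.matrix.nnz else 0.0
    floor = 1e-10 * scaleA * (1.0 + np.abs(Vm).max()) * np.sqrt(Vm.size)
    scale = np.abs(values).sum()
    if abs(values.sum()) > 1e-8 * scale + floor:
        raise SolverError("source field violates Neumann compatibility")
    return SourceField(values=values, mesh=op_Gi.mesh, resolution="fine")


def project_to_coarse(fine_rhs: SourceField, r: int) -> SourceField:
    """Distribute fine-node sources onto the nested coarse node grid.

    Each fine node at fine-edge offsets (dx, dy, dz) inside a coarse cell
    contributes to the 8 surrounding coarse nodes with weight
    ``(r-dx)(r-dy)(r-dz)/r^3`` (and the mirrored expressions) — trilinear
    weights that sum to one per fine node, so total current is conserved.
    """
    if int(r) != r or r < 1:
        raise ValueError("ratio must be an integer >= 1")
    r = int(r)
    fine = fine_rhs.mesh
    fdims = fine.dims
    if any(d % r for d in fdims):
        raise ValueError("fine dimensions not divisible by the ratio")
    cdims = tuple(d // r for d in fdims)
    cS = tuple(d + 1 for d in cdims)
    fS = fine.node_dims
    vals = fine_rhs.values.reshape(fS)

    I, J, K = np.meshgrid(*[np.arange(s) for s in fS], indexing="ij")
    base = [np.minimum(I // r, cdims[0] - 1),
            np.minimum(J // r, cdims[1] - 1),
            np.minimum(K // r, cdims[2] - 1)]
    frac = [I - base[0] * r, J - base[1] * r, K - base[2] * r]

    out = np.zeros(cS)
    for a in (0, 1):
        wx = (r - frac[0]) / r if a == 0 else frac[0] / r
        for b in (0, 1):
            wy = (r - frac[1]) / r if b == 0 else frac[1] / r
            for c in (0, 1):
                wz = (r - frac[2]) / r if c == 0 else frac[2] / r
                w = wx * wy * wz
                np.add.at(
                    out,
                    (base[0] + a, base[1] + b, base[2] + c),
                    w * vals,
                )

    coarse_mesh = ElementMesh(
        dims=cdims,
        spacing=fine.spacing * r,
        origin=fine.origin,
        tissue=np.zeros(cdims, dtype=np.uint8),
        fiber=np.zeros(cdims + (3,)),
        sheet=np.zeros(cdims + (3,)),
        normal=np.zeros(cdims + (3,)),
    )
    return SourceField(values=out.ravel(), mesh=coarse_mesh, resolution="coarse")


def solve_extracellular(
    op_sum: DiscreteOperator,
    rhs: SourceField,
    tol: float = 1e-8,
    solver: EllipticSolver | None = None,
) -> PotentialField:
    """Solve the extracellular system and return the zero-mean potential."""
    if solver is None:
        solver = EllipticSolver(op_sum, tol=tol)
    if rhs.values.shape != (op_sum.n_nodes,):
        raise ValueError("rhs does not match the operator's node grid")
    scale = np.abs(rhs.values).sum()
    scaleA = np.abs(op_sum.matrix.data).max() if op_sum.matrix.nnz else 0.0
    floor = 1e-12 * scaleA * np.sqrt(rhs.values.size) * max(scale, 1.0)
    if abs(rhs.values.sum()) > 1e-8 * scale + floor:
        raise SolverError("rhs violates Neumann compatibility")
    if np.abs(rhs.values).max() <= 1e-9 * scaleA:
        # sub-rounding sources (e.g. a frame at rest) are physically zero
        phi = np.zeros(op_sum.n_nodes)
    else:
        phi = solver.solve(rhs.values)
    cond = op_sum.nodes.conducting_flat()
    phi = phi - phi[cond].mean()
    phi[~cond & ~solver.active] = 0.0
    return PotentialField(values=phi, mesh=op_sum.mesh, nodes=op_sum.nodes)


def sample_lead_voltage(phi: PotentialField, lead, electrodes: ElectrodeSet) -> float:
    """Lead voltage ``sum_i c_i phi(x_i)`` in mV.

    Because the coefficients sum to zero this is invariant to the additive
    gauge of phi.
    """
    v = 0.0
    for name, coeff in lead.terms:
        v += float(coeff) * phi.values[electrodes.flat_node(name)]
    return float(v)


def _block_majority(tissue: np.ndarray, r: int) -> np.ndarray:
    dims = tissue.shape
    cdims = tuple(d // r for d in dims)
    t = tissue.reshape(cdims[0], r, cdims[1], r, cdims[2], r)
    t = t.transpose(0, 2, 4, 1, 3, 5).reshape(*cdims, r**3)
    out = np.zeros(cdims, dtype=np.uint8)
    n_lab = int(tissue.max()) + 1
    counts = np.stack([(t == lab).sum(axis=-1) for lab in range(n_lab)], axis=-1)
    out = np.argmax(counts, axis=-1).astype(np.uint8)
    return out


def coarsen_mesh(fine: ElementMesh, r: int) -> ElementMesh:
    """Coarse companion mesh by majority-vote tissue downsampling.

    Fiber frames on coarse myocardium come from the block orientation
    tensor (principal eigenvector), with the sheet/normal axes rebuilt by
    orthogonalization; ties in the vote resolve to the smallest label.
    """
    if int(r) != r or r < 1:
        raise ValueError("ratio must be an integer >= 1")
    r = int(r)
    if any(d % r for d in fine.dims):
        raise ValueError("fine dimensions not divisible by the ratio")
    cdims = tuple(d // r for d in fine.dims)
    tissue = _block_majority(fine.tissue, r)

    fib = np.zeros(cdims + (3,))
    sht = np.zeros(cdims + (3,))
    nrm = np.zeros(cdims + (3,))
    fib[..., 0] = 1.0
    sht[..., 1] = 1.0
    nrm[..., 2] = 1.0
    aniso = (tissue == Tissue.MYOCARDIUM) | (tissue == Tissue.MUSCLE)
    for ci, cj, ck in np.argwhere(aniso):
        sl = np.s_[ci * r:(ci + 1) * r, cj * r:(cj + 1) * r, ck * r:(ck + 1) * r]
        lab = tissue[ci, cj, ck]
        sel = fine.tissue[sl] == lab
        if not np.any(sel):
            continue
        f = fine.fiber[sl][sel]
        _, vecs = np.linalg.eigh(f.T @ f)
        fvec = vecs[:, -1]
        nn = fine.normal[sl][sel]
        # sign-align normals to the first one before averaging
        nn = nn * np.sign(nn @ nn[0])[:, None]
        nvec = nn.mean(axis=0)
        nvec = nvec - (nvec @ fvec) * fvec
        nl = np.linalg.norm(nvec)
        if nl < 1e-9:
            nvec = np.array([0.0, 0.0, 1.0])
            nvec = nvec - (nvec @ fvec) * fvec
            nl = np.linalg.norm(nvec)
            if nl < 1e-9:
                nvec = np.array([0.0, 1.0, 0.0])
                nvec = nvec - (nvec @ fvec) * fvec
                nl = np.linalg.norm(nvec)
        nvec = nvec / nl
        svec = np.cross(nvec, fvec)
        fib[ci, cj, ck] = fvec
        sht[ci, cj, ck] = svec
        nrm[ci, cj, ck] = nvec
    return ElementMesh(
        dims=cdims,
        spacing=fine.spacing * r,
        origin=fine.origin,
        tissue=tissue,
        fiber=fib,
        sheet=sht,
        normal=nrm,
    )


def electrodes_on_coarse(es: ElectrodeSet, coarse: ElementMesh, r: int) -> ElectrodeSet:
    """Re-place electrodes on the coarse companion mesh.

    Snaps each fine electrode position to the nearest conducting surface
    node of the coarse mesh (plain index division can land on an exterior
    corner of the coarser voxelization)."""
    from .phantom import surface_node_mask

    surf = np.argwhere(surface_node_mask(coarse))
    surf_xyz = np.asarray(coarse.origin) + coarse.spacing * surf
    pos = es.positions_mm()
    ijk = np.zeros((len(es.names), 3), dtype=int)
    for i in range(len(es.names)):
        d = np.linalg.norm(surf_xyz - pos[i], axis=1)
        ijk[i] = surf[int(np.argmin(d))]
    return ElectrodeSet(names=list(es.names), node_ijk=ijk, mesh=coarse)
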