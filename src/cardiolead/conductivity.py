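"""Conductivity tensors and the 19-point finite-difference diffusion operator.

Per-element tensors are built in the local fiber frame,
``G = sigma_L f f^T + sigma_T s s^T + sigma_C n n^T`` (mS/cm), and the
operator ``div(G grad .)`` is discretized on the nodes with element-constant
G.  Face-neighbor couplings come from edge-averaged diagonal tensor entries
(a conservative flux form); edge-diagonal couplings come from node-averaged
off-diagonal entries (centered cross-differences).  The resulting stencil
touches at most the 18 edge/face neighbors plus the center, annihilates
constants row-wise exactly (no-flux boundaries are built in through the
zero conductivity of exterior elements), and is exactly symmetric, which is
what makes the lead-field reciprocity identity hold to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom import ElementMesh, NodeMesh, Tissue, _node_sum

__all__ = [
    "TissueConductivity",
    "ConductivitySet",
    "TensorField",
    "DiscreteOperator",
    "AssemblyError",
    "build_tensor_field",
    "monodomain_tensor",
    "assemble_operator",
    "apply_operator",
]


class AssemblyError(ValueError):
    """Operator or tensor assembly failed a consistency check."""


@dataclass(frozen=True)
class TissueConductivity:
    """Intracellular/extracellular conductivities (mS/cm) along the
    longitudinal (L), transverse (T) and cross-sheet (C) axes, and the
    membrane surface-to-volume ratio beta (cm^-1)."""

    sigma_i: tuple[float, float, float]
    sigma_e: tuple[float, float, float]
    beta: float


#: Default tissue parameters: myocardium is anisotropic in both domains,
#: passive tissues are purely extracellular, skeletal muscle conducts well
#: in-plane but poorly across the subcutaneous sheet.
DEFAULT_TISSUES: dict[Tissue, TissueConductivity] = {
    Tissue.MYOCARDIUM: TissueConductivity((3.0, 0.3, 0.3), (3.00, 1.20, 1.20), 800.0),
    Tissue.BODY: TissueConductivity((0.0, 0.0, 0.0), (2.00, 2.00, 2.00), 0.0),
    Tissue.BLOOD: TissueConductivity((0.0, 0.0, 0.0), (6.00, 6.00, 6.00), 0.0),
    Tissue.LUNG: TissueConductivity((0.0, 0.0, 0.0), (0.50, 0.50, 0.50), 0.0),
    Tissue.MUSCLE: TissueConductivity((0.0, 0.0, 0.0), (3.55, 3.55, 0.44), 0.0),
    Tissue.EXTERIOR: TissueConductivity((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), 0.0),
}


@dataclass
class ConductivitySet:
    """Per-tissue conductivity parameters; defaults to the standard table."""

    tissues: dict[Tissue, TissueConductivity] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )

    def __post_init__(self):
        for t, tc in self.tissues.items():
            if any(s < 0 for s in tc.sigma_i + tc.sigma_e) or tc.beta < 0:
                raise AssemblyError(f"negative conductivity for {t}")
            if t != Tissue.MYOCARDIUM and any(s != 0 for s in tc.sigma_i):
                raise AssemblyError("intracellular sigma must vanish outside myocardium")

    def beta(self, tissue: Tissue = Tissue.MYOCARDIUM) -> float:
        return self.tissues[tissue].beta

    def eigenvalues(self, tissue: Tissue, role: str) -> tuple[float, float, float]:
        tc = self.tissues[tissue]
        if role == "intracellular":
            return tc.sigma_i
        if role == "extracellular":
            return tc.sigma_e
        if role == "bulk":
            return tuple(a + b for a, b in zip(tc.sigma_i, tc.sigma_e))
        if role == "monodomain":
            out = []
            for a, b in zip(tc.sigma_i, tc.sigma_e):
                out.append(a * b / (a + b) if a + b > 0 else 0.0)
            return tuple(out)
        raise AssemblyError(f"unknown tensor role {role!r}")


@dataclass
class TensorField:
    """Per-element symmetric 3x3 conductivity tensors with a role tag."""

    mesh: ElementMesh
    tensors: np.ndarray  # dims + (3, 3), mS/cm
    role: str  # intracellular | extracellular | bulk | monodomain


def build_tensor_field(
    mesh: ElementMesh, cset: ConductivitySet | None = None, role: str = "bulk"
) -> TensorField:
    """Compose per-element tensors from tissue eigenvalues and fiber frames.

    The eigenvalues of each tensor are exactly the tissue's (L, T, C)
    conductivities for the requested role; intracellular (and hence
    monodomain) tensors vanish off myocardium, exterior tensors are zero.
    """
    cset = cset or ConductivitySet()
    mesh.validate_frames()
    dims = mesh.dims
    G = np.zeros(dims + (3, 3))
    frames = np.stack([mesh.fiber, mesh.sheet, mesh.normal], axis=-2)  # (...,3ax,3)
    for t, tc in cset.tissues.items():
        sel = mesh.tissue == int(t)
        if not np.any(sel):
            continue
        sL, sT, sC = cset.eigenvalues(t, role)
        fr = frames[sel]  # (m, 3, 3): rows fiber/sheet/normal
        lam = np.array([sL, sT, sC])
        G[sel] = np.einsum("a,mai,maj->mij", lam, fr, fr)
    return TensorField(mesh=mesh, tensors=G, role=role)


def monodomain_tensor(Gi: TensorField, Ge: TensorField) -> TensorField:
    """Series ("harmonic") combination G_m = G_i G_e / (G_i + G_e).

    Computed per shared eigen-axis; zero wherever the intracellular tensor
    is zero (series conductance with an open circuit).
    """
    if Gi.tensors.shape != Ge.tensors.shape:
        raise AssemblyError("tensor fields on different meshes")
    Gm = np.zeros_like(Gi.tensors)
    active = np.einsum("...ii->...", Gi.tensors) > 0
    gi = Gi.tensors[active]
    ge = Ge.tensors[active]
    lam_sum, vecs = np.linalg.eigh(gi + ge)
    li = np.einsum("mki,mkl,mlj->mij", vecs, gi, vecs)
    le = np.einsum("mki,mkl,mlj->mij", vecs, ge, vecs)
    di = np.einsum("...ii->...i", li)
    de = np.einsum("...ii->...i", le)
    denom = di + de
    lm = np.where(denom > 1e-300, di * de / np.where(denom > 0, denom, 1.0), 0.0)
    Gm[active] = np.einsum("mi,mki,mji->mkj", lm, vecs, vecs)
    return TensorField(mesh=Gi.mesh, tensors=Gm, role="monodomain")


@dataclass
class DiscreteOperator:
    """Sparse 19-point-stencil representation of div(G grad .) over nodes.

    ``matrix`` holds the exactly-symmetric conductance form (entries in mS:
    matrix @ u gives the net current in uA flowing into each node for a
    nodal potential u in mV).  ``apply_density`` divides by the per-node
    control volume (cm^3) to recover the per-volume form uA/cm^3, whose
    interior rows reduce to the familiar sigma * (u_-1 - 2u + u_+1) / h^2.
    Rows of nodes fully decoupled from the conducting region are left empty;
    solvers restrict to the active set.
    """

    matrix: sp.csr_matrix  # conductance form, mS
    nodes: NodeMesh
    mesh: ElementMesh
    node_volumes: np.ndarray  # cm^3, flat
    role: str
    units: str = "matrix: mS (conductance); density form: uA/cm^3 per mV"

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def active_mask(self) -> np.ndarray:
        """Nodes coupled to at least one other node."""
        off = self.matrix.copy()
        off.setdiag(0)
        off.eliminate_zeros()
        return np.asarray(np.abs(off).sum(axis=1)).ravel() > 0

    def apply(self, u: np.ndarray) -> np.ndarray:
        if u.shape != (self.n_nodes,):
            raise ValueError(
                f"field has shape {u.shape}, operator expects ({self.n_nodes},)"
            )
        return self.matrix @ u

    def apply_density(self, u: np.ndarray) -> np.ndarray:
        vol = np.where(self.node_volumes > 0, self.node_volumes, 1.0)
        return self.apply(u) / vol

    def myocardial_form(self) -> sp.csr_matrix:
        """Symmetric restriction of the operator to myocardial nodes.

        Couplings that reach non-myocardial nodes are lumped onto the
        diagonal (the discrete no-flux closure of the intracellular
        boundary condition), so rows still sum to zero exactly and the
        matrix stays symmetric.  Non-myocardial rows are zero.  Cached.
        """
        if getattr(self, "_myo_form", None) is None:
            myo = self.nodes.myocardial_mask().ravel()
            idx = np.flatnonzero(myo)
            n = self.n_nodes
            P = sp.csr_matrix(
                (np.ones(idx.size), (idx, idx)), shape=(n, n)
            )
            core = P @ self.matrix @ P
            r = -np.asarray(core.sum(axis=1)).ravel()
            r[~myo] = 0.0
            self._myo_form = (core + sp.diags(r)).tocsr()
        return self._myo_form

    def to_coo_text(self) -> str:
        """Debug export: 'row col value' lines of the conductance matrix."""
        coo = self.matrix.tocoo()
        return "\n".join(
            f"{r} {c} {v:.17g}" for r, c, v in zip(coo.row, coo.col, coo.data)
        )


def _edge_sum(G_aa: np.ndarray, axis: int) -> np.ndarray:
    """Sum of an element scalar over the up-to-4 elements incident to each
    edge along ``axis``; result indexed by (edge origin node)."""
    trans = [a for a in range(3) if a != axis]
    pad = [(0, 0)] * 3
    for a in trans:
        pad[a] = (1, 1)
    p = np.pad(G_aa, pad)
    s0 = [slice(None)] * 3
    out = None
    for da in (0, 1):
        for db in (0, 1):
            sl = list(s0)
            sl[trans[0]] = slice(da, p.shape[trans[0]] - 1 + da)
            sl[trans[1]] = slice(db, p.shape[trans[1]] - 1 + db)
            term = p[tuple(sl)]
            out = term if out is None else out + term
    return out


def assemble_operator(
    nodes: NodeMesh, G: TensorField, validate: bool = True
) -> DiscreteOperator:
    """Assemble the symmetric 19-point operator for ``div(G grad .)``.

    Elements with off-diagonal tensor entries should lie at least one
    element away from the grid boundary (phantom builders guarantee two);
    out-of-grid cross-couplings are dropped in compensating pairs so row
    sums stay exactly zero.

    Raises
    ------
    AssemblyError
        If the conductivity field is identically zero, or (with
        ``validate``) if symmetry/constant-annihilation checks fail.
    """
    mesh = G.mesh
    if tuple(nodes.dims) != tuple(mesh.node_dims):
        raise AssemblyError("node mesh does not match element mesh")
    if not np.any(G.tensors):
        raise AssemblyError("all-zero conductivity: degenerate operator")
    h = mesh.spacing_cm
    S = mesh.node_dims
    N = int(np.prod(S))
    NI = np.arange(N, dtype=np.int64).reshape(S)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    # face-neighbor couplings from diagonal tensor entries
    for axis in range(3):
        g = h * _edge_sum(G.tensors[..., axis, axis], axis) / 4.0
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        I = NI[tuple(lo)]
        J = NI[tuple(hi)]
        add(I, J, g)
        add(J, I, g)
        add(I, I, -g)
        add(J, J, -g)

    # Edge-diagonal couplings from off-diagonal entries.  For each pair
    # (a, b), the cross term d_a(G_ab d_b u) + d_b(G_ab d_a u) is realized
    # with face-diagonal couplings weighted by G_ab averaged over the TWO
    # elements sharing each diagonal (zero outside the grid), plus a
    # diagonal correction that zeroes every row sum exactly.  The 2-element
    # support means a coupling only exists between corners of an element
    # with nonzero G_ab — the intracellular operator never references
    # nodes outside the myocardium.
    diag_rowsum = np.zeros(N)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        Gab = G.tensors[..., a, b]
        if not np.any(Gab):
            continue
        c = 3 - a - b  # remaining axis
        # average along c over the two elements sharing each face diagonal
        pad = [(0, 0)] * 3
        pad[c] = (1, 1)
        p = np.pad(Gab, pad)
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[c] = slice(0, -1)
        sl1[c] = slice(1, None)
        avg2 = 0.5 * (p[tuple(sl0)] + p[tuple(sl1)])  # c-axis now node-indexed
        g = (h / 2.0) * avg2

        def pair_slice(a_sl, b_sl):
            sl = [slice(None)] * 3
            sl[a] = a_sl
            sl[b] = b_sl
            return tuple(sl)

        # ++ / -- diagonal: positive coupling
        P1 = NI[pair_slice(slice(0, -1), slice(0, -1))]
        Q1 = NI[pair_slice(slice(1, None), slice(1, None))]
        add(P1, Q1, g)
        add(Q1, P1, g)
        np.add.at(diag_rowsum, P1.ravel(), g.ravel())
        np.add.at(diag_rowsum, Q1.ravel(), g.ravel())
        # +- / -+ diagonal: negative coupling
        P2 = NI[pair_slice(slice(0, -1), slice(1, None))]
        Q2 = NI[pair_slice(slice(1, None), slice(0, -1))]
        add(P2, Q2, -g)
        add(Q2, P2, -g)
        np.add.at(diag_rowsum, P2.ravel(), -g.ravel())
        np.add.at(diag_rowsum, Q2.ravel(), -g.ravel())
    if np.any(diag_rowsum):
        nz = np.flatnonzero(diag_rowsum)
        add(nz, nz, -diag_rowsum[nz])

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsr()
    A.sum_duplicates()
    A = (A + A.T) * 0.5  # exact no-op in valid geometries; enforced contract
    A.eliminate_zeros()

    counts = _node_sum(np.ones(mesh.dims))
    volumes = (counts * h**3 / 8.0).ravel()

    op = DiscreteOperator(
        matrix=A.tocsr(),
        nodes=nodes,
        mesh=mesh,
        node_volumes=volumes,
        role=G.role,
    )
    if validate:
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 0:
            raise AssemblyError("assembled operator is not exactly symmetric")
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        scale = max(np.abs(A.data).max(), 1e-300)
        cond = nodes.conducting_flat()
        if np.abs(rowsum[cond]).max() > 1e-12 * scale:
            raise AssemblyError("operator does not annihilate constants")
    return op


def apply_operator(op: DiscreteOperator, u: np.ndarray) -> np.ndarray:
    """Matrix action of the stencil on a nodal field (conductance form)."""
    return op.apply(np.asarray(u, dtype=float))
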