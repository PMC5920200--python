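"""Lead definitions, lead-field solves, gradient downsampling, and the
lead-field ECG.

A lead is a zero-sum combination of electrode potentials.  Its lead field Z
is the potential generated by injecting a unit current through those
electrodes (``div((G_i+G_e) grad Z) = sum_i c_i delta(x - x_i)``, with
``sum|c_i| = 2`` so the injected current is unitary).  By reciprocity of
the symmetric operator, the ECG voltage then becomes a volume integral over
the myocardium, ``V(t) = integral grad Z . G_i grad Vm dx``, evaluated here
as an element-wise quadrature with 4-edge-averaged gradients — cheap enough
to run at every output step of a propagation simulation.

The lead vector field grad Z can be block-downsampled by a factor n either
plainly (LF: mean over each n^3 block) or tissue-selectively (LFS: blocks
containing myocardium average myocardial elements only), the latter
avoiding contamination of the field by its abrupt jumps at, e.g.,
myocardium-lung boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .conductivity import DiscreteOperator, TensorField
from .metrics import ECGTrace
from .monodomain import VmSeries
from .phantom import ElectrodeSet, ElementMesh, Tissue
from .torso import EllipticSolver, SourceField

__all__ = [
    "Lead",
    "LeadField",
    "GradLeadField",
    "standard_leads",
    "solve_lead_field",
    "gradient_field",
    "downsample",
    "evaluate_ecg",
    "adjoint_ecg",
    "ECGRecorder",
    "ecg_from_series",
]


@dataclass(frozen=True)
class Lead:
    """Named zero-sum electrode combination.

    Coefficients are exact rationals so the charge-conservation constraint
    ``sum c_i = 0`` and the unit-current normalization ``sum |c_i| = 2``
    can be enforced exactly.
    """

    name: str
    terms: tuple[tuple[str, Fraction], ...]

    def __post_init__(self):
        coeffs = [Fraction(c) for _, c in self.terms]
        if sum(coeffs) != 0:
            raise ValueError(f"lead {self.name}: coefficients must sum to 0")
        if sum(abs(c) for c in coeffs) != 2:
            raise ValueError(f"lead {self.name}: |coefficients| must sum to 2")

    def coefficient(self, electrode: str) -> Fraction:
        for name, c in self.terms:
            if name == electrode:
                return c
        return Fraction(0)


def _lead(name: str, **coeffs: Fraction) -> Lead:
    return Lead(name, tuple((k, Fraction(v)) for k, v in coeffs.items()))


def standard_leads(es: ElectrodeSet) -> list[Lead]:
    """The 12 standard ECG leads from the 9 standard electrodes.

    Limb leads are bipolar; augmented leads reference each limb against the
    mean of the other two; precordial leads reference the chest electrodes
    against Wilson's central terminal (the mean of RA, LA and LL).
    """
    need = {"RA", "LA", "LL"}
    precordial = [f"V{i}" for i in range(1, 7)]
    have = set(es.names)
    missing = need - have
    if missing:
        raise ValueError(f"missing limb electrodes: {sorted(missing)}")
    half = Fraction(1, 2)
    third = Fraction(1, 3)
    leads = [
        _lead("I", LA=1, RA=-1),
        _lead("II", LL=1, RA=-1),
        _lead("III", LL=1, LA=-1),
        _lead("aVR", RA=1, LA=-half, LL=-half),
        _lead("aVL", LA=1, RA=-half, LL=-half),
        _lead("aVF", LL=1, RA=-half, LA=-half),
    ]
    for v in precordial:
        if v not in have:
            raise ValueError(f"missing precordial electrode {v}")
        leads.append(
            Lead(v, ((v, Fraction(1)), ("RA", -third), ("LA", -third), ("LL", -third)))
        )
    return leads


@dataclass
class LeadField:
    """Nodal lead field Z (mV per unit injected current), zero-mean."""

    values: np.ndarray  # flat nodal
    lead: Lead
    mesh: ElementMesh
    tolerance: float
    resolution: str = "fine"


@dataclass
class GradLeadField:
    """Per-element lead vector field grad Z (mV/cm), possibly block-averaged.

    ``block`` is the downsampling factor (1 = native); ``method`` records
    which averaging rule produced it; ``myo_block`` flags blocks where the
    tissue-selective rule fired (contains myocardium).
    """

    vectors: np.ndarray  # block dims + (3,)
    block: int
    method: str  # "LF" | "LFS" (native gradients are LF with block 1)
    lead: Lead
    fine_dims: tuple[int, int, int]
    myo_block: np.ndarray | None = None


def solve_lead_field(
    op_sum: DiscreteOperator,
    lead: Lead,
    electrodes: ElectrodeSet,
    tol: float = 1e-8,
    solver: EllipticSolver | None = None,
) -> LeadField:
    """Solve for Z with unit nodal current loads at the electrode nodes."""
    if solver is None:
        solver = EllipticSolver(op_sum, tol=tol)
    b = np.zeros(op_sum.n_nodes)
    for name, coeff in lead.terms:
        b[electrodes.flat_node(name)] += float(coeff)
    Z = solver.solve(b, warm_start=False)
    cond = op_sum.nodes.conducting_flat()
    Z = Z - Z[cond].mean()
    return LeadField(values=Z, lead=lead, mesh=op_sum.mesh, tolerance=tol)


def _edge_average_gradient(nodal: np.ndarray, mesh: ElementMesh) -> np.ndarray:
    """Per-element gradient: each component is the mean of the differentials
    along the 4 element edges in that direction, divided by the spacing (cm)."""
    S = mesh.node_dims
    u = nodal.reshape(S)
    h = mesh.spacing_cm
    g = np.empty(mesh.dims + (3,))
    gx = (u[1:, :, :] - u[:-1, :, :])
    g[..., 0] = 0.25 * (gx[:, :-1, :-1] + gx[:, 1:, :-1] + gx[:, :-1, 1:] + gx[:, 1:, 1:]) / h
    gy = (u[:, 1:, :] - u[:, :-1, :])
    g[..., 1] = 0.25 * (gy[:-1, :, :-1] + gy[1:, :, :-1] + gy[:-1, :, 1:] + gy[1:, :, 1:]) / h
    gz = (u[:, :, 1:] - u[:, :, :-1])
    g[..., 2] = 0.25 * (gz[:-1, :-1, :] + gz[1:, :-1, :] + gz[:-1, 1:, :] + gz[1:, 1:, :]) / h
    return g


def gradient_field(Z: LeadField, mesh: ElementMesh | None = None) -> GradLeadField:
    """Element-wise grad Z at native resolution (block size 1)."""
    mesh = mesh or Z.mesh
    g = _edge_average_gradient(Z.values, mesh)
    return GradLeadField(
        vectors=g,
        block=1,
        method="LF",
        lead=Z.lead,
        fine_dims=mesh.dims,
        myo_block=(mesh.tissue == Tissue.MYOCARDIUM),
    )


def downsample(
    grad: GradLeadField,
    n: int,
    method: str = "LF",
    tissue: np.ndarray | None = None,
) -> GradLeadField:
    """Block-average a native-resolution lead vector field by factor n.

    LF averages all fine elements of each n^3 block; LFS averages only the
    myocardial ones whenever the block contains myocardium (and falls back
    to the plain mean otherwise).  Trailing partial blocks average over the
    fine elements available.
    """
    if int(n) != n or n < 1:
        raise ValueError("block factor must be an integer >= 1")
    if method not in ("LF", "LFS"):
        raise ValueError("method must be 'LF' or 'LFS'")
    n = int(n)
    if grad.block != 1:
        raise ValueError("can only downsample a native-resolution field")
    dims = grad.fine_dims
    if tissue is None:
        raise ValueError("tissue labels are required for downsampling")
    bdims = tuple(-(-d // n) for d in dims)
    bi = [np.arange(d) // n for d in dims]
    BI, BJ, BK = np.meshgrid(*bi, indexing="ij")
    myo = tissue == Tissue.MYOCARDIUM

    sums = np.zeros(bdims + (3,))
    counts = np.zeros(bdims)
    np.add.at(sums, (BI, BJ, BK), grad.vectors)
    np.add.at(counts, (BI, BJ, BK), 1.0)
    mean_all = sums / counts[..., None]

    msums = np.zeros(bdims + (3,))
    mcounts = np.zeros(bdims)
    np.add.at(msums, (BI[myo], BJ[myo], BK[myo]), grad.vectors[myo])
    np.add.at(mcounts, (BI[myo], BJ[myo], BK[myo]), 1.0)
    has_myo = mcounts > 0

    if method == "LF":
        vectors = mean_all
    else:
        with np.errstate(invalid="ignore"):
            mean_myo = msums / np.where(mcounts > 0, mcounts, 1.0)[..., None]
        vectors = np.where(has_myo[..., None], mean_myo, mean_all)
    return GradLeadField(
        vectors=vectors,
        block=n,
        method=method,
        lead=grad.lead,
        fine_dims=dims,
        myo_block=has_myo,
    )


class ECGRecorder:
    """Evaluate lead-field ECGs frame by frame (Eq-style element quadrature).

    Precomputes, per myocardial fine element, the 8 corner slots into the
    myocardial Vm vector and the intracellular tensor, then for every frame
    forms ``sum_e (grad Z)_block(e) . G_i,e (grad Vm)_e h^3``.  Works
    identically on the fly (as a run hook) and in post-hoc replay.
    """

    def __init__(
        self,
        grads: list[GradLeadField],
        Gi: TensorField,
        series_template: VmSeries | None = None,
        mesh: ElementMesh | None = None,
        myo_flat: np.ndarray | None = None,
        node_dims: tuple[int, int, int] | None = None,
    ):
        if series_template is not None:
            mesh = series_template.mesh
            myo_flat = series_template.myo_flat
            node_dims = series_template.nodes.dims
        if mesh is None or myo_flat is None or node_dims is None:
            raise ValueError("need a series template or explicit mesh info")
        self.mesh = mesh
        self.grads = grads
        self.lead_names = [g.lead.name for g in grads]
        h = mesh.spacing_cm
        self.volume = h**3
        myo_e = np.argwhere(mesh.tissue == Tissue.MYOCARDIUM)
        self.n_myo_elements = len(myo_e)
        S = node_dims
        flat = lambda ijk: (ijk[:, 0] * S[1] + ijk[:, 1]) * S[2] + ijk[:, 2]
        slot = np.full(int(np.prod(S)), -1, dtype=np.int64)
        slot[myo_flat] = np.arange(len(myo_flat))
        corners = []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    c = slot[flat(myo_e + np.array([dx, dy, dz]))]
                    corners.append(c)
        self.corners = np.stack(corners, axis=0)  # (8, M) slots, all valid
        if np.any(self.corners < 0):
            raise ValueError("myocardial element with non-myocardial corner")
        self.Gi = Gi.tensors[tuple(myo_e.T)]  # (M, 3, 3)
        self.h = h
        # per-lead block lookup of grad Z for each myocardial element
        self.lead_vecs = []
        for g in grads:
            n = g.block
            be = myo_e // n
            self.lead_vecs.append(g.vectors[tuple(be.T)])  # (M, 3)
        self.rows: list[list[float]] = []
        self.times: list[float] = []
        # corner sign patterns for the 4-edge-average gradient
        signs = []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    signs.append((dx, dy, dz))
        self.signs = np.array(signs)  # (8, 3)

    def _grad_vm(self, Vm_myo: np.ndarray) -> np.ndarray:
        u = Vm_myo[self.corners]  # (8, M)
        g = np.empty((self.n_myo_elements, 3))
        for a in range(3):
            w = np.where(self.signs[:, a] == 1, 0.25, -0.25)
            g[:, a] = (w[:, None] * u).sum(axis=0) / self.h
        return g

    def sample(self, Vm_myo: np.ndarray) -> np.ndarray:
        gv = self._grad_vm(Vm_myo)
        J = np.einsum("mij,mj->mi", self.Gi, gv)  # G_i grad Vm
        return np.array(
            [self.volume * float(np.sum(lv * J)) for lv in self.lead_vecs]
        )

    # run-hook protocol
    def __call__(self, idx: int, t_ms: float, Vm_myo: np.ndarray) -> None:
        self.times.append(t_ms)
        self.rows.append(self.sample(Vm_myo))

    def trace(self) -> ECGTrace:
        values = np.asarray(self.rows).T
        return ECGTrace(
            times=np.asarray(self.times),
            lead_names=list(self.lead_names),
            values=values,
        )


def evaluate_ecg(
    grad: GradLeadField,
    Gi: TensorField,
    vm_frame: np.ndarray,
    mesh: ElementMesh,
    myo_flat: np.ndarray | None = None,
) -> float:
    """One lead, one sample of the lead-field ECG (mV).

    ``vm_frame`` is a full nodal field unless ``myo_flat`` maps a compact
    myocardial vector onto the grid.
    """
    S = mesh.node_dims
    if myo_flat is None:
        from .phantom import derive_node_mesh

        nm = derive_node_mesh(mesh)
        myo_flat = np.flatnonzero(nm.myocardial_mask().ravel())
        vm_myo = np.asarray(vm_frame, dtype=float)[myo_flat]
    else:
        vm_myo = np.asarray(vm_frame, dtype=float)
    rec = ECGRecorder(
        [grad], Gi, mesh=mesh, myo_flat=myo_flat, node_dims=S
    )
    return float(rec.sample(vm_myo)[0])


def adjoint_ecg(Z: LeadField, rhs: SourceField) -> float:
    """Discrete Green's-identity form ``<Z, rhs>`` of the lead voltage.

    With the symmetric operator this equals the full-solution voltage
    ``sum_i c_i phi_e(x_i)`` up to solver tolerance — the discrete
    statement of lead-field reciprocity.
    """
    if Z.values.shape != rhs.values.shape:
        raise ValueError("lead field and source field on different meshes")
    return float(Z.values @ rhs.values)


def ecg_from_series(
    grads: list[GradLeadField],
    Gi: TensorField,
    series: VmSeries,
) -> ECGTrace:
    """Post-hoc replay of the lead-field ECG over a stored Vm series."""
    rec = ECGRecorder(grads, Gi, series_template=series)
    for i in range(series.n_frames):
        rec(i, float(series.times_ms[i]), series.frames[i])
    return rec.trace()
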