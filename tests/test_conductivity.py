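"""Tensor construction and the 19-point diffusion stencil."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cardiolead as cl
from cardiolead.conductivity import AssemblyError, ConductivitySet, assemble_operator
from cardiolead.phantom import Tissue


def _uniform_mesh(dims, tissue, frames=None, spacing=1.0):
    t = np.full(dims, int(tissue), dtype=np.uint8)
    f = np.zeros(dims + (3,)); f[..., 0] = 1
    s = np.zeros(dims + (3,)); s[..., 1] = 1
    n = np.zeros(dims + (3,)); n[..., 2] = 1
    if frames is not None:
        f[...], s[...], n[...] = frames
    return cl.ElementMesh(dims, spacing, (0, 0, 0), t, f, s, n)


class TestTensors:
    def test_myocardium_axis_aligned_eigenvalues(self):
        mesh = _uniform_mesh((2, 2, 2), Tissue.MYOCARDIUM)
        Gi = cl.build_tensor_field(mesh, role="intracellular").tensors[0, 0, 0]
        Ge = cl.build_tensor_field(mesh, role="extracellular").tensors[0, 0, 0]
        assert np.allclose(Gi, np.diag([3.0, 0.3, 0.3]))
        assert np.allclose(Ge, np.diag([3.0, 1.2, 1.2]))

    def test_body_is_isotropic_extracellular_only(self):
        mesh = _uniform_mesh((2, 2, 2), Tissue.BODY)
        Ge = cl.build_tensor_field(mesh, role="extracellular").tensors[0, 0, 0]
        Gi = cl.build_tensor_field(mesh, role="intracellular").tensors[0, 0, 0]
        assert np.allclose(Ge, 2.0 * np.eye(3))
        assert np.allclose(Gi, 0.0)

    def test_rotation_transforms_tensor_covariantly(self, rng):
        """For frames rotated by R the tensor must map to R G R^T."""
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        dims = (1, 1, 1)
        frames = (
            np.broadcast_to(q[:, 0], dims + (3,)).copy(),
            np.broadcast_to(q[:, 1], dims + (3,)).copy(),
            np.broadcast_to(q[:, 2], dims + (3,)).copy(),
        )
        mesh = _uniform_mesh(dims, Tissue.MYOCARDIUM, frames)
        G = cl.build_tensor_field(mesh, role="extracellular").tensors[0, 0, 0]
        assert np.allclose(G, q @ np.diag([3.0, 1.2, 1.2]) @ q.T, atol=1e-12)

    def test_nonorthonormal_frame_rejected(self):
        mesh = _uniform_mesh((2, 2, 2), Tissue.MYOCARDIUM)
        mesh.sheet[..., 0] = 0.5  # no longer orthogonal to fiber
        with pytest.raises(cl.ConfigurationError):
            cl.build_tensor_field(mesh, role="bulk")

    def test_monodomain_harmonic_eigenvalues(self):
        cset = ConductivitySet()
        lam = cset.eigenvalues(Tissue.MYOCARDIUM, "monodomain")
        assert lam[0] == pytest.approx(3.0 * 3.0 / 6.0)  # 1.5
        assert lam[1] == pytest.approx(0.3 * 1.2 / 1.5)  # 0.24
        # open circuit: sigma_i = 0 -> sigma_m = 0
        assert cset.eigenvalues(Tissue.LUNG, "monodomain") == (0, 0, 0)

    def test_monodomain_tensor_matches_per_axis_formula(self, small):
        Gi = cl.build_tensor_field(small.mesh, role="intracellular")
        Ge = cl.build_tensor_field(small.mesh, role="extracellular")
        Gm_op = cl.monodomain_tensor(Gi, Ge)
        Gm_direct = cl.build_tensor_field(small.mesh, role="monodomain")
        assert np.allclose(Gm_op.tensors, Gm_direct.tensors, atol=1e-10)


class TestOperator:
    def test_constant_annihilation(self, small_assets):
        op = small_assets.op_sum
        res = op.apply(np.ones(op.n_nodes))
        cond = op.nodes.conducting_flat()
        scale = np.abs(op.matrix.data).max()
        assert np.abs(res[cond]).max() <= 1e-12 * scale

    def test_exact_symmetry(self, small_assets):
        d = abs(small_assets.op_sum.matrix - small_assets.op_sum.matrix.T)
        assert d.nnz == 0 or d.max() == 0.0

    def test_19_point_support(self, small_assets):
        op = small_assets.op_sum
        S = op.nodes.dims
        A = op.matrix.tocoo()
        di = A.row // (S[1] * S[2]) - A.col // (S[1] * S[2])
        dj = (A.row // S[2]) % S[1] - (A.col // S[2]) % S[1]
        dk = A.row % S[2] - A.col % S[2]
        assert np.abs(di).max() <= 1
        assert np.abs(dj).max() <= 1
        assert np.abs(dk).max() <= 1
        # no corner-diagonal couplings
        assert not np.any((np.abs(di) == 1) & (np.abs(dj) == 1) & (np.abs(dk) == 1))

    def test_1d_chain_interior_row_is_second_difference(self):
        """A homogeneous isotropic chain must reduce (in density form) to
        sigma * (u_{i-1} - 2 u_i + u_{i+1}) / h^2 for x-varying fields."""
        sigma, h_mm = 2.0, 1.5
        mesh = _uniform_mesh((12, 1, 1), Tissue.BODY, spacing=h_mm)
        nodes = cl.derive_node_mesh(mesh)
        op = assemble_operator(nodes, cl.build_tensor_field(mesh, role="bulk"))
        S = mesh.node_dims
        rng = np.random.default_rng(1)
        ux = rng.standard_normal(S[0])
        u = np.broadcast_to(ux[:, None, None], S).ravel()
        res = op.apply_density(u).reshape(S)
        h = h_mm / 10.0
        expect = sigma * (ux[:-2] - 2 * ux[1:-1] + ux[2:]) / h**2
        for j in (0, 1):
            for k in (0, 1):
                assert np.allclose(res[1:-1, j, k], expect, rtol=1e-12)

    def test_manufactured_solution_convergence_order(self):
        """div(sigma grad u) for u = sin(ax)cos(by): residual shrinks ~4x
        when h halves (observed order in [1.8, 2.2])."""
        sigma = 2.0
        a, b = 2.0, 3.0  # 1/cm

        def residual(n):
            L_mm = 20.0
            mesh = _uniform_mesh((n, n, n), Tissue.BODY, spacing=L_mm / n)
            nodes = cl.derive_node_mesh(mesh)
            op = assemble_operator(nodes, cl.build_tensor_field(mesh, role="bulk"))
            xyz = mesh.node_coords().reshape(-1, 3) / 10.0  # cm
            u = np.sin(a * xyz[:, 0]) * np.cos(b * xyz[:, 1])
            lap = -sigma * (a**2 + b**2) * u
            res = op.apply_density(u) - lap
            S = mesh.node_dims
            interior = np.zeros(S, dtype=bool)
            interior[3:-3, 3:-3, 3:-3] = True
            return np.abs(res[interior.ravel()]).max()

        e1, e2 = residual(12), residual(24)
        order = np.log2(e1 / e2)
        assert 1.8 <= order <= 2.2

    def test_anisotropic_convergence_order(self):
        """Second order also holds with a rotated anisotropic tensor (the
        cross-derivative stencil terms)."""
        c, s = np.cos(0.4), np.sin(0.4)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        lam = np.diag([3.0, 1.2, 1.2])
        G = R @ lam @ R.T
        aa, bb = 2.0, 3.0

        def residual(n):
            L_mm = 20.0
            dims = (n, n, n)
            frames = (
                np.broadcast_to(R[:, 0], dims + (3,)).copy(),
                np.broadcast_to(R[:, 1], dims + (3,)).copy(),
                np.broadcast_to(R[:, 2], dims + (3,)).copy(),
            )
            mesh = _uniform_mesh(dims, Tissue.MYOCARDIUM, frames, spacing=L_mm / n)
            nodes = cl.derive_node_mesh(mesh)
            op = assemble_operator(
                nodes, cl.build_tensor_field(mesh, role="extracellular")
            )
            xyz = mesh.node_coords().reshape(-1, 3) / 10.0
            u = np.sin(aa * xyz[:, 0]) * np.cos(bb * xyz[:, 1])
            # analytic div(G grad u) with constant G
            uxx = -(aa**2) * u
            uyy = -(bb**2) * u
            uxy = -aa * bb * np.cos(aa * xyz[:, 0]) * np.sin(bb * xyz[:, 1])
            lap = G[0, 0] * uxx + G[1, 1] * uyy + 2 * G[0, 1] * uxy
            res = op.apply_density(u) - lap
            S = mesh.node_dims
            interior = np.zeros(S, dtype=bool)
            interior[3:-3, 3:-3, 3:-3] = True
            return np.abs(res[interior.ravel()]).max()

        e1, e2 = residual(12), residual(24)
        order = np.log2(e1 / e2)
        assert 1.8 <= order <= 2.2

    def test_apply_matches_dense_product(self, tiny_assets, rng):
        op = tiny_assets.op_sum
        dense = op.matrix.toarray()
        u = np.zeros(op.n_nodes)
        idx = rng.choice(op.n_nodes, size=20, replace=False)
        u[idx] = rng.standard_normal(20)
        assert np.allclose(cl.apply_operator(op, u), dense @ u, atol=1e-12)

    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5))
    def test_apply_linearity(self, alpha, beta):
        fx = cl.make_fixture("tiny")
        op = assemble_operator(
            fx.nodes, cl.build_tensor_field(fx.mesh, role="bulk")
        )
        rng = np.random.default_rng(7)
        u = rng.standard_normal(op.n_nodes)
        v = rng.standard_normal(op.n_nodes)
        lhs = op.apply(alpha * u + beta * v)
        rhs = alpha * op.apply(u) + beta * op.apply(v)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_all_zero_conductivity_rejected(self):
        mesh = _uniform_mesh((3, 3, 3), Tissue.EXTERIOR)
        nodes = cl.derive_node_mesh(mesh)
        with pytest.raises(AssemblyError):
            assemble_operator(nodes, cl.build_tensor_field(mesh, role="bulk"))

    def test_coo_text_export_roundtrip(self, tiny_assets):
        txt = tiny_assets.op_sum.to_coo_text()
        rows = [ln.split() for ln in txt.splitlines()]
        import scipy.sparse as sp

        A = sp.coo_matrix(
            (
                [float(v) for _, _, v in rows],
                ([int(r) for r, _, _ in rows], [int(c) for _, c, _ in rows]),
            ),
            shape=tiny_assets.op_sum.matrix.shape,
        )
        assert abs(A.tocsr() - tiny_assets.op_sum.matrix).max() == 0.0
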