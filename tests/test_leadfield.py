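"""Leads, lead-field solves, gradient downsampling, ECG evaluation."""

from fractions import Fraction

import numpy as np
import pytest

import cardiolead as cl
from cardiolead.leadfield import (
    ECGRecorder,
    GradLeadField,
    Lead,
    adjoint_ecg,
    downsample,
    ecg_from_series,
    evaluate_ecg,
    gradient_field,
    solve_lead_field,
    standard_leads,
)
from cardiolead.monodomain import SimulationConfig, StimulusSpec
from cardiolead.phantom import Tissue
from cardiolead.torso import build_rhs, sample_lead_voltage, solve_extracellular


class TestLeadAlgebra:
    def test_every_standard_lead_satisfies_constraints_exactly(self, small):
        for lead in standard_leads(small.electrodes):
            coeffs = [c for _, c in lead.terms]
            assert sum(coeffs) == 0
            assert sum(abs(c) for c in coeffs) == 2

    def test_lead_one_coefficients(self, small):
        lead = next(l for l in standard_leads(small.electrodes) if l.name == "I")
        assert dict(lead.terms) == {"LA": 1, "RA": -1}

    def test_v1_uses_wilson_terminal(self, small):
        v1 = next(l for l in standard_leads(small.electrodes) if l.name == "V1")
        d = dict(v1.terms)
        assert d["V1"] == 1
        assert d["RA"] == d["LA"] == d["LL"] == Fraction(-1, 3)

    def test_avl_augmented_construction(self, small):
        avl = next(l for l in standard_leads(small.electrodes) if l.name == "aVL")
        d = dict(avl.terms)
        assert d["LA"] == 1
        assert d["RA"] == d["LL"] == Fraction(-1, 2)

    def test_unbalanced_lead_rejected(self):
        with pytest.raises(ValueError):
            Lead("bad", (("A", Fraction(1)), ("B", Fraction(-1, 2))))
        with pytest.raises(ValueError):
            Lead("bad", (("A", Fraction(3, 2)), ("B", Fraction(-3, 2))))

    def test_missing_electrode_raises(self, small):
        from cardiolead.phantom import ElectrodeSet

        es = ElectrodeSet(
            names=["RA", "LA"], node_ijk=small.electrodes.node_ijk[:2],
            mesh=small.mesh,
        )
        with pytest.raises(ValueError):
            standard_leads(es)


class TestLeadFieldSolve:
    def test_sign_flip_negates_field(self, small_assets):
        lead_i = next(l for l in small_assets.leads if l.name == "I")
        flipped = Lead("I-", tuple((n, -c) for n, c in lead_i.terms))
        Z = solve_lead_field(
            small_assets.op_sum, lead_i, small_assets.electrodes,
            solver=small_assets.solver,
        )
        Zf = solve_lead_field(
            small_assets.op_sum, flipped, small_assets.electrodes,
            solver=small_assets.solver,
        )
        assert np.allclose(Z.values, -Zf.values, atol=1e-10)

    def test_einthoven_superposition_of_fields(self, small_assets):
        by_name = {Z.lead.name: Z for Z in small_assets.lead_fields}
        diff = by_name["II"].values - by_name["I"].values
        assert np.allclose(by_name["III"].values, diff, atol=1e-6)


class TestGradient:
    def _mesh(self):
        return cl.fixtures.homogeneous_box(6, spacing_mm=2.0)

    def test_linear_field_exact_gradient(self, small_assets):
        mesh = small_assets.mesh
        xyz = mesh.node_coords().reshape(-1, 3) / 10.0  # cm
        slope = 1.7
        Z = cl.LeadField(
            values=slope * xyz[:, 0], lead=small_assets.leads[0],
            mesh=mesh, tolerance=0.0,
        )
        g = gradient_field(Z, mesh)
        assert np.allclose(g.vectors[..., 0], slope, atol=1e-12)
        assert np.allclose(g.vectors[..., 1:], 0.0, atol=1e-12)

    def test_constant_field_zero_gradient(self, small_assets):
        Z = cl.LeadField(
            values=np.full(small_assets.mesh.n_nodes, 4.2),
            lead=small_assets.leads[0], mesh=small_assets.mesh, tolerance=0.0,
        )
        g = gradient_field(Z, small_assets.mesh)
        assert np.all(g.vectors == 0.0)

    def test_single_element_matches_edge_enumeration(self, rng):
        mesh = self._mesh()
        vals = rng.standard_normal(mesh.n_nodes)
        Z = cl.LeadField(values=vals, lead=None, mesh=mesh, tolerance=0.0)
        g = gradient_field(Z, mesh)
        S = mesh.node_dims
        u = vals.reshape(S)
        h = mesh.spacing_cm
        e = (2, 3, 1)
        gx = np.mean([
            u[e[0] + 1, e[1] + b, e[2] + c] - u[e[0], e[1] + b, e[2] + c]
            for b in (0, 1) for c in (0, 1)
        ]) / h
        assert g.vectors[e + (0,)] == pytest.approx(gx, rel=1e-12)


class TestDownsample:
    def _grad(self, dims, vectors, tissue):
        return GradLeadField(
            vectors=vectors, block=1, method="LF", lead=None, fine_dims=dims,
        ), tissue

    def test_identity_at_factor_one(self, rng):
        dims = (4, 4, 4)
        vec = rng.standard_normal(dims + (3,))
        tissue = np.full(dims, int(Tissue.LUNG), dtype=np.uint8)
        tissue[:2] = Tissue.MYOCARDIUM
        g, t = self._grad(dims, vec, tissue)
        for meth in ("LF", "LFS"):
            out = downsample(g, 1, method=meth, tissue=t)
            assert np.array_equal(out.vectors, vec)

    def test_uniform_field_invariant(self):
        dims = (4, 4, 4)
        vec = np.ones(dims + (3,)) * np.array([2.0, -1.0, 0.5])
        tissue = np.full(dims, int(Tissue.BODY), dtype=np.uint8)
        tissue[0, 0, 0] = Tissue.MYOCARDIUM
        g, t = self._grad(dims, vec, tissue)
        for n in (2, 4):
            for meth in ("LF", "LFS"):
                out = downsample(g, n, method=meth, tissue=t)
                assert np.allclose(out.vectors, vec[0, 0, 0], atol=1e-14)

    def test_selective_average_excludes_lung(self):
        """Block of 3 myocardial (1,0,0) and 5 lung (9,0,0) elements:
        LF mean = (6,0,0); LFS myocardium-only mean = (1,0,0)."""
        dims = (2, 2, 2)
        vec = np.full(dims + (3,), 0.0)
        tissue = np.full(dims, int(Tissue.LUNG), dtype=np.uint8)
        myo_idx = [(0, 0, 0), (1, 1, 1), (0, 1, 0)]
        for idx in np.ndindex(dims):
            vec[idx] = [1.0, 0, 0] if idx in myo_idx else [9.0, 0, 0]
        for idx in myo_idx:
            tissue[idx] = Tissue.MYOCARDIUM
        g, t = self._grad(dims, vec, tissue)
        lf = downsample(g, 2, method="LF", tissue=t)
        lfs = downsample(g, 2, method="LFS", tissue=t)
        assert np.allclose(lf.vectors[0, 0, 0], [6.0, 0, 0])
        assert np.allclose(lfs.vectors[0, 0, 0], [1.0, 0, 0])
        assert lfs.myo_block[0, 0, 0]

    def test_trailing_partial_blocks_average_available(self, rng):
        dims = (5, 4, 4)
        vec = rng.standard_normal(dims + (3,))
        tissue = np.full(dims, int(Tissue.BODY), dtype=np.uint8)
        g, t = self._grad(dims, vec, tissue)
        out = downsample(g, 4, method="LF", tissue=t)
        assert out.vectors.shape[:3] == (2, 1, 1)
        assert np.allclose(out.vectors[1, 0, 0], vec[4:5].mean(axis=(0, 1, 2)))

    def test_invalid_factor_rejected(self, rng):
        dims = (4, 4, 4)
        g, t = self._grad(dims, np.zeros(dims + (3,)),
                          np.full(dims, int(Tissue.BODY), dtype=np.uint8))
        with pytest.raises(ValueError):
            downsample(g, 0, tissue=t)


class TestEcgEvaluation:
    def test_constant_vm_gives_zero_every_lead_and_factor(self, small_assets):
        vm = np.full(small_assets.op_sum.n_nodes, -80.0)
        for n in (1, 2):
            for meth in ("LF", "LFS"):
                for g in small_assets.grads(meth, n):
                    v = evaluate_ecg(g, small_assets.Gi, vm, small_assets.mesh)
                    assert v == pytest.approx(0.0, abs=1e-12)

    def test_ecg_linear_in_vm(self, small_assets, small_wave):
        g = small_assets.grads("LF", 1)[0]
        vm = small_wave.frame_full(30)
        rest = small_wave.rest_Vm
        v1 = evaluate_ecg(g, small_assets.Gi, vm, small_assets.mesh)
        v2 = evaluate_ecg(
            g, small_assets.Gi, rest + 2.0 * (vm - rest), small_assets.mesh
        )
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_quadrature_close_to_adjoint_form(self, small_assets, small_wave):
        """Element quadrature vs the nodal Green-identity form: small
        discretization mismatch, not agreement to rounding."""
        i = 40
        rhs = build_rhs(small_assets.op_Gi, small_wave.frame_full(i))
        worst = 0.0
        for Z, g in zip(small_assets.lead_fields, small_assets.grads("LF", 1)):
            va = adjoint_ecg(Z, rhs)
            vq = evaluate_ecg(
                g, small_assets.Gi, small_wave.frame_full(i), small_assets.mesh
            )
            worst = max(worst, abs(va - vq))
        scale = max(
            abs(adjoint_ecg(Z, rhs))
            for Z in small_assets.lead_fields
        )
        assert worst <= 1e-2 * max(scale, 1e-6)


class TestAdjoint:
    def test_zero_rhs(self, small_assets):
        from cardiolead.torso import SourceField

        rhs = SourceField(np.zeros(small_assets.op_sum.n_nodes), small_assets.mesh)
        assert adjoint_ecg(small_assets.lead_fields[0], rhs) == 0.0

    def test_bilinearity_in_rhs(self, small_assets, small_wave):
        rhs = build_rhs(small_assets.op_Gi, small_wave.frame_full(20))
        v = adjoint_ecg(small_assets.lead_fields[0], rhs)
        rhs.values = 2.0 * rhs.values
        assert adjoint_ecg(small_assets.lead_fields[0], rhs) == pytest.approx(
            2 * v, rel=1e-14
        )

    def test_reciprocity_against_full_solution(self, small_assets, rng):
        """c . phi(rhs) == <Z, rhs> for arbitrary myocardial Vm."""
        op = small_assets.op_sum
        myo = small_assets.nodes.myocardial_mask().ravel()
        for _ in range(3):
            vm = np.full(op.n_nodes, -80.0)
            vm[myo] += 100 * rng.random(myo.sum())
            rhs = build_rhs(small_assets.op_Gi, vm)
            phi = solve_extracellular(op, rhs, solver=small_assets.solver)
            for lead, Z in zip(small_assets.leads, small_assets.lead_fields):
                vf = sample_lead_voltage(phi, lead, small_assets.electrodes)
                va = adjoint_ecg(Z, rhs)
                assert abs(vf - va) <= 1e-6 * max(abs(vf), 1e-9)


class TestStreaming:
    def test_trace_shape_counts(self, tiny_assets):
        stim = StimulusSpec(
            site_mm=cl.default_stimulus_sites(tiny_assets.config)[0],
            radius_mm=2 * tiny_assets.mesh.spacing,
        )
        sim = SimulationConfig(duration_ms=5.0, stimulus=stim)
        series = tiny_assets.simulate_site(
            cl.default_stimulus_sites(tiny_assets.config)[0], sim
        )
        trace = tiny_assets.lf_trace(series, 1, "LF")
        assert trace.values.shape == (12, 6)

    def test_on_the_fly_equals_posthoc_replay(self, tiny_assets):
        from cardiolead.monodomain import run

        site = cl.default_stimulus_sites(tiny_assets.config)[0]
        stim = StimulusSpec(site_mm=site, radius_mm=2 * tiny_assets.mesh.spacing)
        cfg = SimulationConfig(duration_ms=20.0, stimulus=stim)
        rec = ECGRecorder(
            tiny_assets.grads("LF", 1), tiny_assets.Gi,
            mesh=tiny_assets.mesh,
            myo_flat=tiny_assets.problem.myo_flat,
            node_dims=tiny_assets.nodes.dims,
        )
        series = run(
            tiny_assets.mesh, tiny_assets.model, cfg,
            problem=tiny_assets.problem, frame_hooks=(rec,),
        )
        online = rec.trace()
        replay = ecg_from_series(tiny_assets.grads("LF", 1), tiny_assets.Gi, series)
        assert np.array_equal(online.values, replay.values)

    def test_einthoven_trace_identity(self, small_assets, small_wave):
        tr = small_assets.lf_trace(small_wave, 1, "LF")
        iii = tr.lead("III")
        diff = tr.lead("II") - tr.lead("I")
        scale = np.abs(iii).max()
        assert np.abs(iii - diff).max() <= 1e-5 * max(scale, 1e-9)
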