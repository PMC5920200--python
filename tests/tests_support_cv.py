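"""Shared helper: conduction-velocity measurement on the reference strand."""

import numpy as np

import cardiolead as cl
from cardiolead.conductivity import TissueConductivity
from cardiolead.fixtures import strand_mesh
from cardiolead.membrane import MitchellSchaeffer
from cardiolead.monodomain import (
    MonodomainProblem,
    SimulationConfig,
    StimulusSpec,
    activation_times,
    run,
)
from cardiolead.phantom import Tissue


def scaled_conductivities(scale: float) -> cl.ConductivitySet:
    cset = cl.ConductivitySet()
    tc = cset.tissues[Tissue.MYOCARDIUM]
    cset.tissues[Tissue.MYOCARDIUM] = TissueConductivity(
        tuple(s * scale for s in tc.sigma_i),
        tuple(s * scale for s in tc.sigma_e),
        tc.beta,
    )
    return cset


def measure_strand_cv(scale: float = 1.0) -> float:
    """Planar-wave conduction velocity (mm/ms) on a 0.2 mm strand at the
    default 10 us step, with all myocardial conductivities scaled."""
    mesh = strand_mesh(n_long=150, cross=2, spacing_mm=0.2)
    model = MitchellSchaeffer()
    prob = MonodomainProblem(mesh, model, scaled_conductivities(scale))
    stim = StimulusSpec(site_mm=(0.4, 0.4, 0.4), radius_mm=1.0, amplitude=30.0)
    cfg = SimulationConfig(dt_ms=0.01, output_every=10, duration_ms=70.0,
                           stimulus=stim)
    series = run(mesh, model, cfg, problem=prob)
    ijk = np.stack(np.unravel_index(prob.myo_flat, mesh.node_dims), axis=-1)
    center = (ijk[:, 1] == 2) & (ijk[:, 2] == 2)
    x = ijk[center, 0] * mesh.spacing
    act = activation_times(series)[center]
    sel = (x > 8) & (x < 24) & np.isfinite(act)
    return float(np.polyfit(act[sel], x[sel], 1)[0])
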