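"""End-to-end experiments: phantom -> propagation -> ECGs by four methods.

``ExperimentAssets`` assembles everything that depends only on the
geometry (operators, electrodes, lead fields and their downsampled
gradients, the coarse companion mesh); ``run_experiment`` then loops over
stimulus sites, runs the monodomain model once per site, evaluates the
requested ECG methods and writes traces, a comparison report and a
reproducibility manifest.

Method names: ``FSF`` (fine-mesh full solution), ``FSC`` (coarse full
solution with projected sources), ``LF(n)`` / ``LFS(n)`` (lead-field ECG
with plain / tissue-selective gradient downsampling by factor n).
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .conductivity import ConductivitySet, assemble_operator, build_tensor_field
from .leadfield import (
    ECGRecorder,
    GradLeadField,
    downsample,
    ecg_from_series,
    gradient_field,
    solve_lead_field,
    standard_leads,
)
from .membrane import MembraneModel, MitchellSchaeffer
from .metrics import ECGTrace, compare_methods
from .monodomain import (
    MonodomainProblem,
    SimulationConfig,
    StimulusSpec,
    VmSeries,
    run,
)
from .phantom import (
    ConfigurationError,
    PhantomConfig,
    build_phantom,
    default_electrode_positions,
    default_stimulus_sites,
    derive_node_mesh,
    place_electrodes,
)
from .torso import (
    EllipticSolver,
    build_rhs,
    coarsen_mesh,
    electrodes_on_coarse,
    project_to_coarse,
    sample_lead_voltage,
    solve_extracellular,
)

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "ExperimentAssets",
    "run_experiment",
    "parse_method",
]

_METHOD_RE = re.compile(r"^(LFS?|FSF|FSC)(?:\((\d+)\))?$")


def load_experiment_toml(path) -> "ExperimentConfig":
    """Read an experiment description from TOML.

    Sections ``[phantom]``, ``[simulation]`` and ``[experiment]`` override
    the respective dataclass defaults field by field (tuple-valued fields
    accept TOML arrays)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    def build(cls, section):
        kw = {}
        for k, v in data.get(section, {}).items():
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kw[k] = v
        return cls(**kw)

    phantom = build(PhantomConfig, "phantom")
    sim = build(SimulationConfig, "simulation")
    exp_kw = dict(data.get("experiment", {}))
    if "methods" in exp_kw:
        exp_kw["methods"] = tuple(exp_kw["methods"])
    if "stimulus_sites" in exp_kw:
        exp_kw["stimulus_sites"] = tuple(
            tuple(s) for s in exp_kw["stimulus_sites"]
        )
    return ExperimentConfig(phantom=phantom, sim=sim, **exp_kw)


def parse_method(name: str) -> tuple[str, int | None]:
    m = _METHOD_RE.match(name)
    if not m:
        raise ConfigurationError(f"unknown ECG method {name!r}")
    kind, n = m.group(1), m.group(2)
    if kind in ("FSF", "FSC"):
        if n is not None:
            raise ConfigurationError(f"{kind} takes no downsampling factor")
        return kind, None
    return kind, int(n) if n is not None else 1


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[str, ...] = ("FSF", "FSC", "LF(1)", "LF(2)", "LF(5)",
                                "LFS(2)", "LFS(5)")
    reference: str = "LF(1)"
    stimulus_sites: tuple | None = None  # None -> 7 default shell sites
    tol: float = 1e-8
    outdir: str = "experiment_out"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    artifacts: dict[str, str]
    versions: dict[str, str]
    wall_times_s: dict[str, float]
    seed: int

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class ExperimentAssets:
    """Geometry-dependent artifacts shared by all ECG methods and sites."""

    def __init__(
        self,
        phantom: PhantomConfig,
        tol: float = 1e-8,
        model: MembraneModel | None = None,
        cset: ConductivitySet | None = None,
        need_coarse: bool = True,
    ):
        self.config = phantom
        self.tol = tol
        self.model = model or MitchellSchaeffer()
        self.cset = cset or ConductivitySet()
        self.mesh = build_phantom(phantom)
        self.nodes = derive_node_mesh(self.mesh, self.cset.beta())
        positions = phantom.electrodes or default_electrode_positions(phantom)
        self.electrodes = place_electrodes(self.mesh, positions)
        self.leads = standard_leads(self.electrodes)
        self.Gi = build_tensor_field(self.mesh, self.cset, "intracellular")
        Gsum = build_tensor_field(self.mesh, self.cset, "bulk")
        self.op_Gi = assemble_operator(self.nodes, self.Gi)
        self.op_sum = assemble_operator(self.nodes, Gsum)
        self.solver = EllipticSolver(self.op_sum, tol=tol)
        self.problem = MonodomainProblem(
            self.mesh, self.model, self.cset, nodes=self.nodes
        )
        self.lead_fields = [
            solve_lead_field(self.op_sum, lead, self.electrodes, solver=self.solver)
            for lead in self.leads
        ]
        self.native_grads = [gradient_field(Z, self.mesh) for Z in self.lead_fields]
        self._grad_cache: dict[tuple[str, int], list[GradLeadField]] = {}

        self.coarse = None
        if need_coarse and phantom.coarse_ratio > 1:
            r = phantom.coarse_ratio
            cmesh = coarsen_mesh(self.mesh, r)
            cnodes = derive_node_mesh(cmesh, self.cset.beta())
            cGsum = build_tensor_field(cmesh, self.cset, "bulk")
            cop = assemble_operator(cnodes, cGsum)
            self.coarse = {
                "ratio": r,
                "mesh": cmesh,
                "nodes": cnodes,
                "op_sum": cop,
                "solver": EllipticSolver(cop, tol=tol),
                "electrodes": electrodes_on_coarse(self.electrodes, cmesh, r),
            }

    def grads(self, method: str, n: int) -> list[GradLeadField]:
        """Downsampled lead vector fields for every lead (cached)."""
        key = (method, n)
        if key not in self._grad_cache:
            self._grad_cache[key] = [
                downsample(g, n, method=method, tissue=self.mesh.tissue)
                for g in self.native_grads
            ]
        return self._grad_cache[key]

    # ---- ECG methods -------------------------------------------------
    def lf_trace(self, series: VmSeries, n: int = 1, method: str = "LF") -> ECGTrace:
        return ecg_from_series(self.grads(method, n), self.Gi, series)

    def fsf_trace(self, series: VmSeries) -> ECGTrace:
        rows = []
        for i in range(series.n_frames):
            rhs = build_rhs(self.op_Gi, series.frame_full(i))
            phi = solve_extracellular(self.op_sum, rhs, solver=self.solver)
            rows.append(
                [sample_lead_voltage(phi, lead, self.electrodes) for lead in self.leads]
            )
        return ECGTrace(
            times=series.times_ms,
            lead_names=[l.name for l in self.leads],
            values=np.asarray(rows).T,
        )

    def fsc_trace(self, series: VmSeries) -> ECGTrace:
        if self.coarse is None:
            raise ConfigurationError("no coarse mesh configured")
        c = self.coarse
        rows = []
        for i in range(series.n_frames):
            rhs = build_rhs(self.op_Gi, series.frame_full(i))
            crhs = project_to_coarse(rhs, c["ratio"])
            crhs.mesh = c["mesh"]
            phi = solve_extracellular(c["op_sum"], crhs, solver=c["solver"])
            rows.append(
                [sample_lead_voltage(phi, lead, c["electrodes"]) for lead in self.leads]
            )
        return ECGTrace(
            times=series.times_ms,
            lead_names=[l.name for l in self.leads],
            values=np.asarray(rows).T,
        )

    def trace_for(self, method: str, series: VmSeries) -> ECGTrace:
        kind, n = parse_method(method)
        if kind == "FSF":
            return self.fsf_trace(series)
        if kind == "FSC":
            return self.fsc_trace(series)
        return self.lf_trace(series, n=n, method=kind)

    def simulate_site(self, site, sim: SimulationConfig) -> VmSeries:
        stim = StimulusSpec(
            site_mm=tuple(site), radius_mm=2 * self.mesh.spacing, amplitude=30.0
        )
        cfg = SimulationConfig(
            dt_ms=sim.dt_ms,
            output_every=sim.output_every,
            duration_ms=sim.duration_ms,
            stimulus=stim,
            seed=sim.seed,
        )
        return run(self.mesh, self.model, cfg, problem=self.problem)


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Run every requested method at every stimulus site and write a report.

    Produces, per site, one ECG CSV per method plus a site report comparing
    each trace with the configured reference; a summary report aggregates
    RelDif over sites (mean and standard deviation per method).  Output is
    deterministic for a fixed config.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in cfg.methods:
        parse_method(m)
    if cfg.reference not in cfg.methods:
        raise ConfigurationError("reference method must be among methods")
    walls: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    t0 = time.perf_counter()
    assets = ExperimentAssets(
        cfg.phantom, tol=cfg.tol,
        need_coarse=any(parse_method(m)[0] == "FSC" for m in cfg.methods),
    )
    walls["setup"] = time.perf_counter() - t0

    sites = (
        list(cfg.stimulus_sites)
        if cfg.stimulus_sites is not None
        else default_stimulus_sites(cfg.phantom)
    )
    all_rows = []
    for s_idx, site in enumerate(sites):
        t0 = time.perf_counter()
        series = assets.simulate_site(site, cfg.sim)
        walls[f"site{s_idx}_propagation"] = time.perf_counter() - t0
        traces = {}
        for m in cfg.methods:
            t0 = time.perf_counter()
            traces[m] = assets.trace_for(m, series)
            walls[f"site{s_idx}_{m}"] = time.perf_counter() - t0
            path = outdir / f"ecg_site{s_idx}_{m.replace('(', '_').rstrip(')')}.csv"
            traces[m].to_csv(path, metadata={"method": m, "site": s_idx})
            artifacts[f"site{s_idx}:{m}"] = str(path)
        table, _ = compare_methods(traces, cfg.reference)
        table.insert(0, "site", s_idx)
        all_rows.append(table)
    report = pd.concat(all_rows, ignore_index=True)
    summary = (
        report.groupby("trace", sort=False)["reldif"]
        .agg(["mean", "std", "median"])
        .reset_index()
    )
    report_path = outdir / "report.csv"
    summary_path = outdir / "report_summary.csv"
    report.to_csv(report_path, index=False, float_format="%.8g")
    summary.to_csv(summary_path, index=False, float_format="%.8g")
    artifacts["report"] = str(report_path)
    artifacts["summary"] = str(summary_path)

    import cardiolead

    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        artifacts=artifacts,
        versions={
            "cardiolead": cardiolead.__version__,
            "numpy": np.__version__,
        },
        wall_times_s={k: round(v, 3) for k, v in walls.items()},
        seed=cfg.seed,
    )
    manifest.save(outdir / "manifest.json")
    return manifest
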