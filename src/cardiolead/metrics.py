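"""ECG traces and comparison statistics (RelDif, RMS, maximum difference).

RelDif pools all leads and samples jointly:
``sqrt( sum_t sum_n (V - Vref)^2 / sum_t sum_n Vref^2 )`` — a scale-free
measure of waveform disagreement; RMS and the maximum difference carry the
units of the traces (mV).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ECGTrace",
    "ErrorReport",
    "reldif",
    "rms_and_max",
    "compare_methods",
]


@dataclass
class ECGTrace:
    """Simulated ECG: uniformly sampled values (mV) for named leads."""

    times: np.ndarray  # (T,) ms
    lead_names: list[str]
    values: np.ndarray  # (L, T) mV

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.lead_names), self.times.size):
            raise ValueError("trace shape does not match leads x samples")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9 * max(abs(dt[0]), 1)):
                raise ValueError("trace is not uniformly sampled")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    def lead(self, name: str) -> np.ndarray:
        return self.values[self.lead_names.index(name)]

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Write `time_ms` plus one column per lead, with `#` metadata lines."""
        with open(path, "w") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            df = pd.DataFrame(
                {"time_ms": self.times}
                | {name: self.values[i] for i, name in enumerate(self.lead_names)}
            )
            df.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ECGTrace":
        with open(path) as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        df = pd.read_csv(io.StringIO("".join(lines)))
        names = [c for c in df.columns if c != "time_ms"]
        return cls(
            times=df["time_ms"].to_numpy(),
            lead_names=names,
            values=df[names].to_numpy().T,
        )


def _aligned(V: ECGTrace, Vref: ECGTrace) -> tuple[np.ndarray, np.ndarray]:
    vals = V.values
    if V.lead_names != Vref.lead_names:
        if set(V.lead_names) != set(Vref.lead_names):
            raise ValueError("traces have different lead sets")
        order = [V.lead_names.index(n) for n in Vref.lead_names]
        vals = vals[order]
    if vals.shape != Vref.values.shape:
        raise ValueError("traces have different shapes")
    if not (np.all(np.isfinite(vals)) and np.all(np.isfinite(Vref.values))):
        raise ValueError("trace contains NaN")
    return vals, Vref.values


def reldif(V: ECGTrace, Vref: ECGTrace) -> float:
    """Relative difference pooled over all leads and samples."""
    a, b = _aligned(V, Vref)
    denom = float(np.sum(b * b))
    if denom == 0:
        raise ValueError("reference trace has zero norm")
    return float(np.sqrt(np.sum((a - b) ** 2) / denom))


def rms_and_max(V: ECGTrace, Vref: ECGTrace) -> tuple[float, float]:
    """Pooled RMS difference and maximum absolute difference (mV)."""
    a, b = _aligned(V, Vref)
    d = a - b
    return float(np.sqrt(np.mean(d * d))), float(np.abs(d).max())


@dataclass
class ErrorReport:
    """Trace-vs-reference statistics with a per-lead breakdown."""

    name: str
    reldif: float
    rms_mV: float
    max_mV: float
    per_lead: pd.DataFrame  # columns: lead, reldif, rms_mV, max_mV


def _per_lead(V: ECGTrace, Vref: ECGTrace) -> pd.DataFrame:
    rows = []
    a, b = _aligned(V, Vref)
    ref_denom = np.sum(b**2, axis=1)
    for i, lead in enumerate(Vref.lead_names):
        d = a[i] - b[i]
        rows.append(
            {
                "lead": lead,
                "reldif": (
                    float(np.sqrt(np.sum(d**2) / ref_denom[i]))
                    if ref_denom[i] > 0
                    else np.inf
                ),
                "rms_mV": float(np.sqrt(np.mean(d**2))),
                "max_mV": float(np.abs(d).max()),
            }
        )
    return pd.DataFrame(rows)


def compare_methods(
    traces: dict[str, ECGTrace], reference: str
) -> tuple[pd.DataFrame, dict[str, ErrorReport]]:
    """Compare every trace against the named reference.

    Returns a summary table (one row per non-reference trace, in input
    order) and the full reports with per-lead breakdowns.
    """
    if reference not in traces:
        raise KeyError(f"reference trace {reference!r} not provided")
    ref = traces[reference]
    reports: dict[str, ErrorReport] = {}
    rows = []
    for name, tr in traces.items():
        if name == reference:
            continue
        rd = reldif(tr, ref)
        rms, mx = rms_and_max(tr, ref)
        reports[name] = ErrorReport(
            name=name, reldif=rd, rms_mV=rms, max_mV=mx, per_lead=_per_lead(tr, ref)
        )
        rows.append({"trace": name, "reldif": rd, "rms_mV": rms, "max_mV": mx})
    return pd.DataFrame(rows), reports
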