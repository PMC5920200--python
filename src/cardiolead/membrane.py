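"""Membrane kinetics: the ionic-model interface and per-step integrators.

The tissue model is agnostic to the ionic model: anything exposing an
ionic current I_ion(Vm, state), gate kinetics (y_inf, tau)(Vm) and rates for
non-gating variables can drive propagation.  Gates are advanced with the
Rush-Larsen exponential update (exact for voltage-frozen rates over one
step, and unconditionally bounded), everything else with forward Euler.

The shipped default is a two-variable Mitchell-Schaeffer model: a normalized
potential u with a cubic inward current gated by a single recovery variable.
It is not a human ventricular cell model, but it produces a propagating
action potential with a realistic upstroke, plateau and repolarization
within a 500 ms beat, which is all the ECG machinery requires.  Plugging in
a different model means implementing the MembraneModel interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntegrationError",
    "MembraneState",
    "MembraneModel",
    "MitchellSchaeffer",
    "rush_larsen_step",
    "forward_euler_step",
    "eval_membrane",
]


class IntegrationError(RuntimeError):
    pass


def rush_larsen_step(y, y_inf, tau, dt: float):
    """Exponential gate update ``y_inf + (y - y_inf) * exp(-dt/tau)``.

    Exact for constant (y_inf, tau) over the step; the result always lies
    between y and y_inf, so gates started in [0, 1] stay in [0, 1].
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("gate time constant must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    y = np.asarray(y, dtype=float)
    if dt == 0:
        return y.copy() if y.ndim else float(y)  # exact identity
    return y_inf + (y - y_inf) * np.exp(-dt / tau)


def forward_euler_step(y, dydt, dt: float):
    """Explicit Euler update ``y + dt * dydt``."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return np.asarray(y, dtype=float) + dt * np.asarray(dydt, dtype=float)


@dataclass
class MembraneState:
    """Per-node membrane state: Vm (mV), gating variables in [0,1], and any
    non-gating state variables."""

    Vm: np.ndarray  # (n,)
    gates: np.ndarray  # (n, n_gates)
    other: np.ndarray  # (n, n_other)

    def copy(self) -> "MembraneState":
        return MembraneState(self.Vm.copy(), self.gates.copy(), self.other.copy())


class MembraneModel:
    """Interface for ionic models.

    Subclasses define the pair (I_ion, F): the transmembrane ionic current
    density and the state-evolution rates, split into gates (integrated by
    Rush-Larsen) and other variables (forward Euler).
    """

    n_gates: int = 0
    n_other: int = 0
    C_m: float = 1.0  # uF/cm^2
    V_rest: float = -80.0  # mV

    def rest_state(self, n: int) -> MembraneState:
        raise NotImplementedError

    def gate_kinetics(self, Vm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (y_inf, tau) per gate, shapes (n, n_gates); tau in ms."""
        raise NotImplementedError

    def ionic_current(self, Vm, gates, other) -> np.ndarray:
        """I_ion in uA/cm^2 (positive = outward, i.e. repolarizing)."""
        raise NotImplementedError

    def other_rates(self, Vm, gates, other) -> np.ndarray:
        return np.zeros_like(other)


@dataclass
class MitchellSchaeffer(MembraneModel):
    """Two-variable Mitchell-Schaeffer ventricular surrogate.

    Normalized potential ``u = (Vm - V_rest) / amplitude``; the single gate
    h recovers with tau_open below the threshold and closes with tau_close
    above it.  du/dt = h u^2 (1-u)/tau_in - u/tau_out.  With the defaults
    the action potential lasts roughly 250 ms and the resting state
    (u = 0, h = 1) is an exact fixed point.
    """

    tau_in: float = 0.3  # ms
    tau_out: float = 6.0  # ms
    tau_open: float = 120.0  # ms
    tau_close: float = 150.0  # ms
    u_gate: float = 0.13  # threshold on normalized potential
    V_rest: float = -80.0  # mV
    amplitude: float = 100.0  # mV
    C_m: float = 1.0  # uF/cm^2
    n_gates: int = 1
    n_other: int = 0

    def rest_state(self, n: int) -> MembraneState:
        return MembraneState(
            Vm=np.full(n, self.V_rest),
            gates=np.ones((n, 1)),
            other=np.zeros((n, 0)),
        )

    def _u(self, Vm):
        return (np.asarray(Vm, dtype=float) - self.V_rest) / self.amplitude

    def gate_kinetics(self, Vm):
        u = self._u(Vm)
        below = u < self.u_gate
        y_inf = np.where(below, 1.0, 0.0)[:, None]
        tau = np.where(below, self.tau_open, self.tau_close)[:, None]
        return y_inf, tau

    def ionic_current(self, Vm, gates, other):
        u = self._u(Vm)
        hgate = gates[:, 0]
        dudt = hgate * u * u * (1.0 - u) / self.tau_in - u / self.tau_out
        # C_m dVm/dt = -I_ion  =>  I_ion = -C_m * amplitude * du/dt
        return -self.C_m * self.amplitude * dudt


def eval_membrane(
    model: MembraneModel, state: MembraneState, dt: float
) -> tuple[MembraneState, np.ndarray]:
    """Advance the membrane state one step (diffusion excluded).

    Gates move by Rush-Larsen, other variables by forward Euler; I_ion is
    evaluated with the updated state and returned alongside for the Vm
    update.  ``dt = 0`` returns the state unchanged exactly.
    """
    if not np.all(np.isfinite(state.Vm)):
        bad = int(np.flatnonzero(~np.isfinite(state.Vm))[0])
        raise IntegrationError(f"non-finite Vm at node {bad}")
    y_inf, tau = model.gate_kinetics(state.Vm)
    gates = rush_larsen_step(state.gates, y_inf, tau, dt)
    if state.other.size:
        other = forward_euler_step(
            state.other, model.other_rates(state.Vm, gates, state.other), dt
        )
    else:
        other = state.other
    I_ion = model.ionic_current(state.Vm, gates, other)
    return MembraneState(Vm=state.Vm, gates=gates, other=other), I_ion
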