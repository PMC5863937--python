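"""Derived observables: probability flux densities, gating currents and
moved charge, pulse-limited and steady-state activation curves, Boltzmann
fits.

Gating current per channel is computed from the model, not measured: each
voltage-dependent step contributes e * z_step * J_step(t), where J is the
net probability flux density through the step (s^-1) and e the elementary
charge.  The sign convention is activation-positive: flux in the forward
(activating) direction counts positive, so ON-gating currents during a
hyperpolarizing pulse are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .schemes import (
    E_CHARGE,
    KineticScheme,
    ParameterSet,
    charge_potential,
    transition_rates,
)
from .simulate import (
    Propagator,
    Trajectory,
    VoltageProtocol,
    simulate_protocol,
    stationary_distribution,
)


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""


@dataclass
class FluxSeries:
    """Net probability flux density J(t) per reversible transition,
    activation-direction positive, units s^-1."""

    times: np.ndarray
    flux: np.ndarray                      # shape (n_times, n_transitions)
    labels: list[str]
    scheme: KineticScheme

    def through(self, label: str) -> np.ndarray:
        return self.flux[:, self.labels.index(label)]


@dataclass
class GatingCurrent:
    """Computed per-channel gating current and cumulative moved charge."""

    times: np.ndarray
    current: np.ndarray                   # total I_g(t), amperes per channel
    per_step: np.ndarray                  # (n_times, n_transitions)
    labels: list[str]
    charge: np.ndarray                    # cumulative Q(t)/e, elementary charges

    @property
    def total_charge(self) -> float:
        return float(self.charge[-1])


@dataclass
class ActivationCurve:
    """P_o at the end of a pulse of fixed duration (or at steady state)
    across a voltage range."""

    voltages: np.ndarray
    po: np.ndarray
    t_pulse: float | str = "infinite"


@dataclass
class BoltzmannFit:
    z: float
    v_half: float
    amplitude: float
    residual: float


def flux_density(traj: Trajectory) -> FluxSeries:
    """J_step(t) = k_f(V) p_from(t) - k_b(V) p_to(t) for every transition,
    with the sample's segment voltage."""
    scheme, params = traj.scheme, traj.params
    idx = {s: i for i, s in enumerate(scheme.state_names)}
    n_t = len(traj.times)
    J = np.zeros((n_t, len(scheme.transitions)))
    for vi, V in enumerate(np.unique(traj.voltages)):
        sel = traj.voltages == V
        for k, t in enumerate(scheme.transitions):
            kf, kb = transition_rates(scheme, t, params, V)
            J[sel, k] = (
                kf * traj.occupancy[sel, idx[t.from_state]]
                - kb * traj.occupancy[sel, idx[t.to_state]]
            )
    return FluxSeries(
        times=traj.times,
        flux=J,
        labels=[t.label for t in scheme.transitions],
        scheme=scheme,
    )


def gating_current(traj: Trajectory, exclude_charges: tuple[str, ...] = ()) -> GatingCurrent:
    """Per-channel gating current I_g(t) = e * sum_steps z_step * J_step(t).

    ``exclude_charges`` drops steps whose charge parameter is listed (e.g.
    ("zc",) to omit the buffer-state contribution).  Cumulative charge is
    the trapezoid integral of I_g divided by e.
    """
    fx = flux_density(traj)
    scheme, params = traj.scheme, traj.params
    z = np.array(
        [
            0.0
            if (t.charge is None or t.charge in exclude_charges)
            else params[t.charge]
            for t in scheme.transitions
        ]
    )
    per_step = E_CHARGE * fx.flux * z[None, :]
    total = per_step.sum(axis=1)
    q = cumulative_trapezoid(total, traj.times, initial=0.0) / E_CHARGE
    return GatingCurrent(
        times=traj.times,
        current=total,
        per_step=per_step,
        labels=fx.labels,
        charge=q,
    )


def charge_moved(
    scheme: KineticScheme,
    params: ParameterSet,
    p_start: np.ndarray,
    p_end: np.ndarray,
    exclude_charges: tuple[str, ...] = (),
) -> float:
    """Exact total gating charge moved between two occupancy vectors,
    from the per-state charge potential (independent oracle for the
    integrated gating current)."""
    if exclude_charges:
        vals = dict(params.values)
        for name in exclude_charges:
            vals[name] = 0.0
        params = ParameterSet(vals, V_T=params.V_T)
    w = charge_potential(scheme, params)
    return float((p_end - p_start) @ w)


def peak_gating_current(gc: GatingCurrent) -> tuple[float, float]:
    """(time, amplitude) of the gating-current peak, refined by a parabola
    through the discrete maximum and its neighbours."""
    k = int(np.argmax(gc.current))
    if 0 < k < len(gc.current) - 1:
        y0, y1, y2 = gc.current[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            dt = gc.times[k + 1] - gc.times[k]
            t_pk = gc.times[k] + delta * dt
            i_pk = y1 - 0.25 * (y0 - y2) * delta
            return float(t_pk), float(i_pk)
    return float(gc.times[k]), float(gc.current[k])


def steady_state_activation(
    scheme: KineticScheme,
    params: ParameterSet,
    voltages,
    t_pulse: float | str = "infinite",
    holding: float = 0.0,
    sample_dt: float = 1e-3,
) -> ActivationCurve:
    """P_o(V) at the end of a ``t_pulse``-second pulse from the holding
    potential, or the true stationary P_o for t_pulse="infinite"."""
    voltages = np.asarray(list(voltages), dtype=float)
    if voltages.size == 0:
        raise ValueError("voltages must be nonempty")
    mask = scheme.conducting_mask
    po = np.empty(len(voltages))
    if t_pulse == "infinite":
        for i, V in enumerate(voltages):
            po[i] = stationary_distribution(scheme, params, V)[mask].sum()
    else:
        prop = Propagator(scheme, params)
        p_hold = prop.stationary(holding)
        for i, V in enumerate(voltages):
            p_end = prop.propagate(p_hold, V, np.array([float(t_pulse)]))[0]
            po[i] = p_end[mask].sum()
    return ActivationCurve(voltages=voltages, po=po, t_pulse=t_pulse)


def boltzmann(V, z, v_half, amplitude, V_T):
    return amplitude / (1.0 + np.exp(z * (V - v_half) / V_T))


def boltzmann_fit(curve: ActivationCurve, V_T: float) -> BoltzmannFit:
    """Least-squares Boltzmann fit amplitude / (1 + exp(z (V - V_h) / V_T)).

    With z > 0 the curve activates on hyperpolarization, the HCN
    convention.  Raises FitFailureError on non-sigmoidal input.
    """
    V, po = np.asarray(curve.voltages, float), np.asarray(curve.po, float)
    if len(V) < 4:
        raise FitFailureError("need at least 4 voltage points spanning the transition")
    amp0 = max(po.max(), 1e-6)
    half = amp0 / 2.0
    v0 = float(V[np.argmin(np.abs(po - half))])

    def resid(x):
        return boltzmann(V, x[0], x[1], x[2], V_T) - po

    sol = least_squares(
        resid, x0=[5.0, v0, amp0], bounds=([0.0, -400.0, 0.0], [50.0, 200.0, 1.5])
    )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or rms > 0.2 * max(amp0, 1e-6):
        raise FitFailureError(
            f"Boltzmann fit failed (success={sol.success}, rms={rms:.3g}, "
            f"x={sol.x}); input may not be sigmoidal"
        )
    return BoltzmannFit(
        z=float(sol.x[0]), v_half=float(sol.x[1]), amplitude=float(sol.x[2]),
        residual=rms,
    )


def activation_step_trajectory(
    scheme: KineticScheme,
    params: ParameterSet,
    v_step: float,
    duration: float,
    holding: float = 0.0,
    sample_dt: float = 2e-4,
) -> Trajectory:
    """Convenience: equilibrate at ``holding`` and step to ``v_step``; the
    standard input to gating-current and flux computations."""
    proto = VoltageProtocol(
        holding=holding, segments=[(v_step, duration)], sample_dt=sample_dt
    )
    return simulate_protocol(scheme, params, proto)
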