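"""Synthetic P_o trace sets with the statistical structure of averaged
patch-clamp recordings.

The study design is a grid of 27 double-pulse protocols per condition:
from a 0 mV holding potential, an activating pulse to V_a lasting t_a,
then a deactivating pulse to V_d.  Nine (V_a, t_a) pairs are crossed with
three deactivation voltages.  Each experimental trace is the average of
5-18 patches; the generator emulates that by drawing per-patch noisy
replicates (additive recording noise plus a multiplicative patch-to-patch
scale jitter), averaging them, and emitting the mean P_o with its
empirical s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import Trace, TraceSet
from .schemes import KineticScheme, ParameterSet
from .simulate import Propagator, VoltageProtocol, open_probability, simulate_protocol

#: Activation voltages (mV) and pulse durations (s) per condition; crossed
#: with the shared deactivation voltages below this gives the 27 protocols.
ACTIVATION_GRID = {
    "no_cAMP": [(-140.0, (0.3, 1.0, 4.0)),
                (-125.0, (0.5, 2.0, 11.0)),
                (-110.0, (1.5, 5.0, 15.0))],
    "cAMP": [(-130.0, (0.15, 0.3, 3.0)),
             (-100.0, (0.5, 2.0, 11.0)),
             (-90.0, (1.5, 5.0, 15.0))],
}

#: Deactivation voltages (mV), common to both conditions.
DEACTIVATION_VOLTAGES = (-40.0, 20.0, 80.0)

#: Deactivation segment duration (s); tails at -40 mV complete well within
#: this window for both selected models.
T_DEACT_DEFAULT = 2.0


@dataclass
class NoiseModel:
    """Per-point noise of an averaged P_o trace.

    A single patch contributes additive Gaussian noise with standard
    deviation a + b*sqrt(P_o(1-P_o)) (baseline recording noise plus an
    occupancy-dependent term) and a multiplicative amplitude jitter of
    relative scale ``patch_jitter``.  Averaging n patches shrinks the
    spread by sqrt(n).  Synthetic-only: real s.e.m. bands come from the
    recordings themselves.
    """

    a: float = 0.005
    b: float = 0.03
    patch_jitter: float = 0.05

    def patch_sigma(self, po: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.sqrt(np.clip(po * (1.0 - po), 0.0, None))

    def sigma(self, po: np.ndarray, n_patches: int) -> np.ndarray:
        """Expected s.e.m. of the n-patch average."""
        return self.patch_sigma(po) / np.sqrt(n_patches)

    @property
    def is_zero(self) -> bool:
        return self.a == 0.0 and self.b == 0.0 and self.patch_jitter == 0.0

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(a=0.0, b=0.0, patch_jitter=0.0)


def make_protocols(
    condition: str,
    t_deact: float = T_DEACT_DEFAULT,
    holding: float = 0.0,
    sample_dt: float = 1e-3,
) -> list[VoltageProtocol]:
    """The 27 double-pulse protocols of one condition, ordered by
    activation voltage, then pulse duration, then deactivation voltage."""
    if condition not in ACTIVATION_GRID:
        raise KeyError(f"condition must be one of {sorted(ACTIVATION_GRID)}, got {condition!r}")
    protocols = []
    for v_a, durations in ACTIVATION_GRID[condition]:
        for t_a in durations:
            for v_d in DEACTIVATION_VOLTAGES:
                protocols.append(
                    VoltageProtocol(
                        holding=holding,
                        segments=[(v_a, t_a), (v_d, t_deact)],
                        sample_dt=sample_dt,
                        name=f"Va{v_a:+.0f}_ta{t_a:g}_Vd{v_d:+.0f}",
                    )
                )
    assert len(protocols) == 27
    return protocols


def generate_traceset(
    scheme: KineticScheme,
    params: ParameterSet,
    protocols: list[VoltageProtocol],
    noise: NoiseModel | None = None,
    n_patches_range: tuple[int, int] = (5, 18),
    seed: int = 0,
    condition: str = "",
) -> TraceSet:
    """Simulate each protocol, add averaged-patch noise, return a TraceSet.

    Deterministic per seed.  With a zero NoiseModel the emitted means equal
    the clean simulation exactly and sigma falls back to the expected-sem
    formula evaluated with the default NoiseModel (so weights stay finite).
    """
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    prop = Propagator(scheme, params)
    traces = []
    patch_counts = []
    lo, hi = n_patches_range
    for proto in protocols:
        traj = simulate_protocol(scheme, params, proto, propagator=prop)
        clean = open_probability(traj)
        n = int(rng.integers(lo, hi + 1))
        patch_counts.append(n)
        if noise.is_zero:
            mean = clean
            sem = NoiseModel().sigma(clean, n)
        elif n == 1:
            # single sweep: no empirical s.e.m.; declare the model sigma
            sig = noise.patch_sigma(clean)
            scale = 1.0 + noise.patch_jitter * rng.standard_normal()
            mean = scale * clean + sig * rng.standard_normal(len(clean))
            sem = sig
        else:
            sig = noise.patch_sigma(clean)
            scales = 1.0 + noise.patch_jitter * rng.standard_normal(n)
            reps = scales[:, None] * clean[None, :] + sig[None, :] * rng.standard_normal(
                (n, len(clean))
            )
            mean = reps.mean(axis=0)
            sem = reps.std(axis=0, ddof=1) / np.sqrt(n)
        traces.append(
            Trace(protocol=proto, times=traj.times.copy(), po=mean, sigma=sem)
        )
    return TraceSet(
        traces=traces,
        condition=condition,
        meta={"seed": seed, "n_patches": patch_counts},
    )


def current_from_po(
    po: np.ndarray,
    voltages: np.ndarray,
    conductance_pS: float,
    reversal_mV: float,
    n_channels: float,
) -> np.ndarray:
    """Ohmic macroscopic current I = N * g * (V - V_rev) * P_o, amperes.

    Samples at the reversal potential carry zero driving force; P_o cannot
    be recovered there, so ``po_from_current`` masks them with NaN.
    """
    g = conductance_pS * 1e-12                 # S
    drive = (np.asarray(voltages, float) - reversal_mV) * 1e-3   # V
    return n_channels * g * drive * np.asarray(po, float)


def po_from_current(
    current: np.ndarray,
    voltages: np.ndarray,
    conductance_pS: float,
    reversal_mV: float,
    n_channels: float,
) -> np.ndarray:
    """Invert current_from_po; exact in the noise-free case.  Zero-driving-
    force samples are returned as NaN."""
    g = conductance_pS * 1e-12
    drive = (np.asarray(voltages, float) - reversal_mV) * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        po = np.asarray(current, float) / (n_channels * g * drive)
    po = np.where(np.abs(drive) < 1e-12, np.nan, po)
    return po
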