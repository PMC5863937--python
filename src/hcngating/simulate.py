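"""Master-equation propagation through piecewise-constant voltage protocols.

Occupancy row-vectors p(t) obey dp/dt = p Q(V); within a segment the
voltage, hence Q, is constant, so p(t) = p(0) expm(Q t).  Propagation uses
an eigendecomposition of Q cached per voltage (the schemes are small and
the protocols use few voltages), falling back to scaling-and-squaring
matrix exponentials when the eigenvector basis is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .schemes import KineticScheme, ParameterSet, SchemeError, generator_matrix

#: eigenvector condition number beyond which expm stepping is used instead
EIG_COND_LIMIT = 1e8


class NoUniqueStationaryError(SchemeError):
    """The generator is reducible: no unique stationary distribution."""


@dataclass
class VoltageProtocol:
    """Ordered (voltage mV, duration s) segments applied from a holding
    potential, sampled on a uniform grid of ``sample_dt`` seconds."""

    holding: float
    segments: list[tuple[float, float]]
    sample_dt: float = 1e-3
    name: str = ""

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for v, dur in self.segments:
            if not dur > 0:
                raise ValueError(f"segment durations must be positive, got {dur}")
        if not self.sample_dt > 0:
            raise ValueError("sample_dt must be positive")
        if self.sample_dt > min(d for _, d in self.segments) + 1e-15:
            raise ValueError("sample_dt must not exceed the shortest segment")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)

    def voltage_at(self, t: float) -> float:
        acc = 0.0
        for v, dur in self.segments:
            acc += dur
            if t <= acc + 1e-12:
                return v
        return self.segments[-1][0]


@dataclass
class Trajectory:
    """State occupancies over time for one scheme under one protocol."""

    times: np.ndarray
    occupancy: np.ndarray          # shape (n_times, n_states)
    voltages: np.ndarray           # segment voltage at each sample
    scheme: KineticScheme
    params: ParameterSet
    protocol: VoltageProtocol | None = None

    @property
    def state_names(self) -> list[str]:
        return self.scheme.state_names

    def occupancy_of(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.scheme.state_index(state)]


class Propagator:
    """Caches per-voltage eigendecompositions of the generator for one
    (scheme, params) pair; reused across protocols inside a global fit."""

    def __init__(self, scheme: KineticScheme, params: ParameterSet):
        self.scheme = scheme
        self.params = params
        self._cache: dict[float, tuple] = {}

    def _decomposition(self, V: float):
        dec = self._cache.get(V)
        if dec is None:
            Q = generator_matrix(self.scheme, self.params, V)
            lam, U = np.linalg.eig(Q)
            cond = np.linalg.cond(U)
            Uinv = np.linalg.inv(U) if cond < EIG_COND_LIMIT else None
            dec = (Q, lam, U, Uinv)
            self._cache[V] = dec
        return dec

    def propagate(self, p0: np.ndarray, V: float, times: np.ndarray) -> np.ndarray:
        """Occupancies at ``times`` (seconds after segment start) for a
        segment held at voltage ``V`` with initial occupancy ``p0``."""
        Q, lam, U, Uinv = self._decomposition(V)
        if Uinv is not None:
            c = p0 @ U                                   # modal coefficients
            # clip exp argument: decaying modes only, but guard overflow for
            # round-off-positive eigenvalues
            ex = np.exp(np.minimum(np.outer(times, lam), 700.0))
            out = np.real((c[None, :] * ex) @ Uinv)
            # conservation by construction: the modal reconstruction loses
            # ~eps*||Q|| per unit time on stiff segments; project back onto
            # the probability simplex normalization
            out /= out.sum(axis=1, keepdims=True)
            return out
        # defective / ill-conditioned basis: step with expm
        out = np.empty((len(times), len(p0)))
        p = p0
        t_prev = 0.0
        for k in np.argsort(times):
            dt = times[k] - t_prev
            if dt > 0:
                p = p @ expm(Q * dt)
            out[k] = p
            t_prev = times[k]
        return out

    def stationary(self, V: float) -> np.ndarray:
        Q, *_ = self._decomposition(V)
        return _stationary_from_Q(Q)


def _stationary_from_Q(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    # uniqueness needs an irreducible chain: strong connectivity on the
    # numerically nonzero rates (an absolute floor marks de-facto zeros;
    # relative thresholds would misfire on stiff generators whose rates
    # legitimately span ~18 decades at extreme voltages)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix((np.abs(Q) > 1e-100).astype(int))
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        raise NoUniqueStationaryError(
            "generator is reducible: stationary state not unique"
        )
    # Grassmann-Taksar-Heyman state elimination: subtraction-free, so it
    # stays accurate even when rates span many decades (stiff generators
    # at extreme voltages defeat naive linear solves)
    q = np.abs(np.where(np.eye(n, dtype=bool), 0.0, Q))
    for m in range(n - 1, 0, -1):
        s = q[m, :m].sum()
        if s <= 0.0:
            raise NoUniqueStationaryError("generator appears reducible or degenerate")
        q[:m, m] /= s
        q[:m, :m] += np.outer(q[:m, m], q[m, :m])
        q[np.diag_indices(m)] -= np.diag(np.outer(q[:m, m], q[m, :m]))
    p = np.zeros(n)
    p[0] = 1.0
    for m in range(1, n):
        p[m] = p[:m] @ q[:m, m]
    return p / p.sum()


def stationary_distribution(
    scheme: KineticScheme, params: ParameterSet, V: float
) -> np.ndarray:
    """Unique stationary occupancy vector p with p Q = 0 and sum(p) = 1."""
    return _stationary_from_Q(generator_matrix(scheme, params, V))


def _segment_times(duration: float, dt: float, include_start: bool) -> np.ndarray:
    n = int(np.floor(duration / dt + 1e-9))
    t = dt * np.arange(0 if include_start else 1, n + 1)
    if not len(t) or duration - t[-1] > 1e-9 * max(1.0, duration):
        t = np.append(t, duration)
    else:
        t[-1] = duration
    return t


def simulate_protocol(
    scheme: KineticScheme,
    params: ParameterSet,
    protocol: VoltageProtocol,
    initial="stationary_at_holding",
    propagator: Propagator | None = None,
) -> Trajectory:
    """Propagate occupancies through a protocol's segments.

    ``initial`` is either an occupancy vector or the string
    "stationary_at_holding" (the default: the channel equilibrated at the
    holding potential before the sweep, the usual experimental situation).
    """
    prop = propagator or Propagator(scheme, params)
    if isinstance(initial, str):
        if initial != "stationary_at_holding":
            raise ValueError(f"unknown initial condition {initial!r}")
        p0 = prop.stationary(protocol.holding)
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (scheme.n_states,):
            raise ValueError("initial occupancy has wrong length")
        if abs(p0.sum() - 1.0) > 1e-8:
            raise ValueError("initial occupancy must sum to 1")

    all_t, all_p, all_v = [], [], []
    t_offset = 0.0
    p = p0
    for i, (V, dur) in enumerate(protocol.segments):
        t_local = _segment_times(dur, protocol.sample_dt, include_start=(i == 0))
        occ = prop.propagate(p, V, t_local)
        all_t.append(t_offset + t_local)
        all_p.append(occ)
        all_v.append(np.full(len(t_local), V))
        p = occ[-1]                      # t_local always ends exactly at dur
        t_offset += dur
    return Trajectory(
        times=np.concatenate(all_t),
        occupancy=np.vstack(all_p),
        voltages=np.concatenate(all_v),
        scheme=scheme,
        params=params,
        protocol=protocol,
    )


def open_probability(traj: Trajectory) -> np.ndarray:
    """P_o(t): total occupancy of the conducting states."""
    return traj.occupancy[:, traj.scheme.conducting_mask].sum(axis=1)
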