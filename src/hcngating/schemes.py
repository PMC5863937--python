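"""Kinetic schemes for voltage-gated channel gating.

A :class:`KineticScheme` is a reversible Markov state model of channel
gating: states are channel conformations (conducting or not), transitions
are reversible steps with voltage-dependent rates of single-barrier Eyring
form, and constraints encode microscopic reversibility (detailed balance
around cycles) and a fixed saturating open probability.

Rates follow

    k_f(V) = k_f0 * exp(-z * q_f * V / V_T)
    k_b(V) = k_b0 * exp(+z * q_b * V / V_T)

with ``z`` the effective gating charge of the full step (elementary
charges), ``q_f + q_b = 1`` the charge partition across the barrier
(symmetric, 0.5/0.5, by default) and ``V_T = RT/F`` the thermal voltage in
mV.  With this sign convention hyperpolarization (negative V) accelerates
the forward (activating) rates, as appropriate for HCN channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

#: Thermal voltage RT/F in mV (~22 degC, Xenopus excised-patch conditions).
V_T_DEFAULT = 25.4

#: Elementary charge in coulombs.
E_CHARGE = 1.602e-19


class SchemeError(ValueError):
    """Malformed scheme, parameters or constraint."""


class MissingParameterError(SchemeError, KeyError):
    """A rate or charge symbol required by the scheme has no value."""


class InvalidConstantError(SchemeError):
    """A physical constant is out of its admissible range (e.g. V_T <= 0)."""


class InfeasibleConstraintError(SchemeError):
    """A constraint cannot be satisfied with positive rates."""


class UnbalancedCycleError(SchemeError):
    """A cycle's step charges do not cancel, so detailed balance cannot
    hold at every voltage."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpec:
    """A channel conformation; ``conducting`` marks open states."""

    name: str
    conducting: bool = False


@dataclass(frozen=True)
class RateLaw:
    """Numeric voltage-dependent rate of one direction of a step.

    ``partition`` is the fraction of the step charge ``z`` carried by this
    direction; the forward and backward laws of one step partition z
    between them (default symmetric split).
    """

    k0: float
    z: float = 0.0
    direction: str = "forward"
    partition: float = 0.5

    def __post_init__(self):
        if not self.k0 > 0:
            raise SchemeError(f"rate k0 must be positive, got {self.k0}")
        if self.z < 0:
            raise SchemeError(f"gating charge must be >= 0, got {self.z}")
        if not 0.0 <= self.partition <= 1.0:
            raise SchemeError(f"partition must lie in [0, 1], got {self.partition}")
        if self.direction not in ("forward", "backward"):
            raise SchemeError(f"direction must be forward/backward, got {self.direction}")


def rate_at_voltage(law: RateLaw, V: float, V_T: float = V_T_DEFAULT) -> float:
    """Evaluate a rate law at membrane voltage ``V`` (mV).

    Forward rates are k0*exp(-z*partition*V/V_T), backward rates
    k0*exp(+z*partition*V/V_T); at V = 0 or z = 0 the rate is exactly k0.
    """
    if not V_T > 0:
        raise InvalidConstantError(f"thermal voltage must be positive, got {V_T}")
    if not math.isfinite(V):
        raise SchemeError(f"voltage must be finite, got {V}")
    sign = -1.0 if law.direction == "forward" else 1.0
    return law.k0 * math.exp(sign * law.z * law.partition * V / V_T)


@dataclass(frozen=True)
class TransitionSpec:
    """A reversible step between two states.

    Rate constants are referenced by parameter *name* (resolved against a
    :class:`ParameterSet`), so schemes stay symbolic for fitting and
    constraint derivation.  ``charge`` names a shared gating-charge
    parameter (z1, z2, zc, ...); ``None`` marks a voltage-independent step.
    ``stoich_f``/``stoich_b`` are fixed multiplicative factors
    (stoichiometric or allosteric) applied to the zero-voltage rates.
    """

    from_state: str
    to_state: str
    kf: str
    kb: str
    charge: str | None = None
    partition: float = 0.5
    stoich_f: float = 1.0
    stoich_b: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.partition <= 1.0:
            raise SchemeError(f"partition must lie in [0, 1], got {self.partition}")
        if self.stoich_f <= 0 or self.stoich_b <= 0:
            raise SchemeError("stoichiometric factors must be positive")

    @property
    def label(self) -> str:
        return f"{self.from_state}->{self.to_state}"


@dataclass(frozen=True)
class ConstraintSpec:
    """A parameter constraint.

    kinds:
      * ``detailed_balance`` — ``cycle`` is an ordered ring of state names;
        ``derived`` names the one zero-voltage rate solved from microscopic
        reversibility (clockwise product = counter-clockwise product).
      * ``posat`` — ``derived`` (a closing rate) is set to
        ``open_rate * (1 - p_open_sat) / p_open_sat`` so that the final
        closed-open equilibrium saturates at open probability p_open_sat.
      * ``fixed`` — parameters in ``names`` are pinned (excluded from fits).
      * ``shared`` — parameters in ``names`` are aliases of one value.
    """

    kind: str
    cycle: tuple[str, ...] = ()
    derived: str = ""
    open_rate: str = ""
    p_open_sat: float | None = None
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("detailed_balance", "posat", "fixed", "shared"):
            raise SchemeError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "posat":
            if self.p_open_sat is None or not 0.0 < self.p_open_sat < 1.0:
                raise SchemeError("p_open_sat must lie in (0, 1)")
            if not self.derived or not self.open_rate:
                raise SchemeError("posat constraint needs open_rate and derived names")
        if self.kind == "detailed_balance":
            if len(self.cycle) < 3:
                raise SchemeError("detailed-balance cycle needs >= 3 states")
            if not self.derived:
                raise SchemeError("detailed-balance constraint needs a derived rate name")


@dataclass
class ParameterSet:
    """Named rate constants (s^-1, at 0 mV) and gating charges, plus the
    thermal voltage used to evaluate voltage dependence."""

    values: dict[str, float] = field(default_factory=dict)
    V_T: float = V_T_DEFAULT

    def __post_init__(self):
        if not self.V_T > 0:
            raise InvalidConstantError(f"thermal voltage must be positive, got {self.V_T}")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise MissingParameterError(f"parameter {name!r} has no value") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name, default=None):
        return self.values.get(name, default)

    def updated(self, **changes: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(changes)
        return ParameterSet(vals, V_T=self.V_T)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), V_T=self.V_T)


@dataclass
class KineticScheme:
    """States + reversible transitions + constraints of one gating model."""

    name: str
    states: list[StateSpec]
    transitions: list[TransitionSpec]
    constraints: list[ConstraintSpec] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.array([s.conducting for s in self.states], dtype=bool)

    def transition_between(self, a: str, b: str) -> tuple[TransitionSpec, int]:
        """Return (transition, orientation): +1 if the transition's forward
        direction is a->b, -1 if it is b->a."""
        for t in self.transitions:
            if t.from_state == a and t.to_state == b:
                return t, +1
            if t.from_state == b and t.to_state == a:
                return t, -1
        raise SchemeError(f"no transition between {a!r} and {b!r}")

    def rate_parameter_names(self) -> list[str]:
        names: list[str] = []
        for t in self.transitions:
            for n in (t.kf, t.kb):
                if n not in names:
                    names.append(n)
        return names

    def charge_parameter_names(self) -> list[str]:
        names: list[str] = []
        for t in self.transitions:
            if t.charge is not None and t.charge not in names:
                names.append(t.charge)
        return names

    def parameter_names(self) -> list[str]:
        return self.rate_parameter_names() + self.charge_parameter_names()

    def derived_names(self) -> list[str]:
        return [c.derived for c in self.constraints if c.derived]

    def free_parameter_names(self) -> list[str]:
        """All parameters minus constraint-derived ones (fixed/shared
        assignments are a fitting concern, not a scheme one)."""
        derived = set(self.derived_names())
        return [n for n in self.parameter_names() if n not in derived]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = self.state_names
        if len(set(names)) != len(names):
            raise SchemeError(f"duplicate state names in scheme {self.name!r}")
        if not any(s.conducting for s in self.states):
            raise SchemeError("scheme needs at least one conducting state")
        if not any(not s.conducting for s in self.states):
            raise SchemeError("scheme needs at least one non-conducting state")
        known = set(names)
        for t in self.transitions:
            if t.from_state not in known or t.to_state not in known:
                raise SchemeError(f"transition {t.label} references unknown state")
        g = nx.Graph()
        g.add_nodes_from(names)
        g.add_edges_from((t.from_state, t.to_state) for t in self.transitions)
        if len(names) > 1 and not nx.is_connected(g):
            raise SchemeError(f"transition graph of {self.name!r} is not connected")
        # every independent cycle must have zero net step charge, otherwise
        # detailed balance cannot hold at all voltages
        for cyc in nx.cycle_basis(g):
            dz = self.cycle_charge(tuple(cyc), None)
            if dz is not None and abs(dz) > 1e-9:
                raise UnbalancedCycleError(
                    f"cycle {cyc} carries net step charge {dz:+.3g}; "
                    "equal charges must cancel around every cycle"
                )
        derived = self.derived_names()
        if len(set(derived)) != len(derived):
            raise SchemeError("a derived rate appears in more than one constraint")

    def cycle_charge(self, cycle: tuple[str, ...], params: "ParameterSet | None") -> float | None:
        """Signed sum of step charges traversing ``cycle`` once.

        Charges are parameters; without a ParameterSet the sum can only be
        formed symbolically — returns the signed sum assuming each distinct
        charge symbol has unit value times its multiplicity, which detects
        imbalance whenever symbols do not cancel (None if they do not share
        symbols but could still cancel numerically — not possible here
        since charges are nonnegative).
        """
        weights: dict[str, float] = {}
        m = len(cycle)
        for i in range(m):
            a, b = cycle[i], cycle[(i + 1) % m]
            t, orient = self.transition_between(a, b)
            if t.charge is None:
                continue
            weights[t.charge] = weights.get(t.charge, 0.0) + orient
        if params is None:
            # symbolic: cancels iff every symbol's multiplicity is zero
            return sum(abs(w) for w in weights.values())
        return sum(w * params[z] for z, w in weights.items())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "hcngating-scheme-v1",
            "name": self.name,
            "states": [{"name": s.name, "conducting": s.conducting} for s in self.states],
            "transitions": [
                {
                    "from": t.from_state,
                    "to": t.to_state,
                    "kf": t.kf,
                    "kb": t.kb,
                    "charge": t.charge,
                    "partition": t.partition,
                    "stoich_f": t.stoich_f,
                    "stoich_b": t.stoich_b,
                }
                for t in self.transitions
            ],
            "constraints": [
                {
                    "kind": c.kind,
                    "cycle": list(c.cycle),
                    "derived": c.derived,
                    "open_rate": c.open_rate,
                    "p_open_sat": c.p_open_sat,
                    "names": list(c.names),
                }
                for c in self.constraints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        states = [StateSpec(s["name"], bool(s["conducting"])) for s in d["states"]]
        transitions = [
            TransitionSpec(
                t["from"], t["to"], t["kf"], t["kb"],
                charge=t.get("charge"),
                partition=t.get("partition", 0.5),
                stoich_f=t.get("stoich_f", 1.0),
                stoich_b=t.get("stoich_b", 1.0),
            )
            for t in d["transitions"]
        ]
        constraints = [
            ConstraintSpec(
                c["kind"],
                cycle=tuple(c.get("cycle", ())),
                derived=c.get("derived", ""),
                open_rate=c.get("open_rate", ""),
                p_open_sat=c.get("p_open_sat"),
                names=tuple(c.get("names", ())),
            )
            for c in d["constraints"]
        ]
        return cls(d["name"], states, transitions, constraints)

    def with_partition(self, partition: float) -> "KineticScheme":
        """Copy of the scheme with every voltage-dependent step's charge
        partition set to ``partition`` (for sensitivity analyses)."""
        ts = [
            replace(t, partition=partition) if t.charge is not None else t
            for t in self.transitions
        ]
        return KineticScheme(self.name, list(self.states), ts, list(self.constraints))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def transition_rates(
    scheme: KineticScheme, t: TransitionSpec, params: ParameterSet, V: float
) -> tuple[float, float]:
    """(forward, backward) rate of one step at voltage ``V``."""
    z = params[t.charge] if t.charge is not None else 0.0
    fwd = RateLaw(params[t.kf] * t.stoich_f, z, "forward", t.partition)
    bwd = RateLaw(params[t.kb] * t.stoich_b, z, "backward", 1.0 - t.partition)
    return rate_at_voltage(fwd, V, params.V_T), rate_at_voltage(bwd, V, params.V_T)


def generator_matrix(scheme: KineticScheme, params: ParameterSet, V: float) -> np.ndarray:
    """Master-equation generator Q at voltage ``V``.

    Q[i, j] (i != j) is the rate of the i->j transition; diagonal entries
    make every row sum to zero, so occupancy row-vectors evolve as
    dp/dt = p Q.
    """
    n = scheme.n_states
    idx = {name: i for i, name in enumerate(scheme.state_names)}
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        kf, kb = transition_rates(scheme, t, params, V)
        i, j = idx[t.from_state], idx[t.to_state]
        Q[i, j] += kf
        Q[j, i] += kb
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


def _zero_voltage_rate(t: TransitionSpec, orient: int, params: ParameterSet) -> float:
    """Zero-voltage rate of traversing transition ``t`` in orientation
    ``orient`` (+1 forward, -1 backward), including stoichiometric factors."""
    if orient > 0:
        return params[t.kf] * t.stoich_f
    return params[t.kb] * t.stoich_b


def apply_constraints(scheme: KineticScheme, params: ParameterSet) -> ParameterSet:
    """Fill in constraint-derived rates and return a completed ParameterSet.

    posat constraints are resolved first (a detailed-balance cycle may
    involve the posat-derived closing rate), then detailed-balance cycles.
    """
    out = params.copy()
    for c in scheme.constraints:
        if c.kind == "shared":
            ref = c.names[0]
            for alias in c.names[1:]:
                out = out.updated(**{alias: out[ref]})
    for c in scheme.constraints:
        if c.kind == "posat":
            k_open = out[c.open_rate]
            k_close = k_open * (1.0 - c.p_open_sat) / c.p_open_sat
            if not k_close > 0:
                raise InfeasibleConstraintError(
                    f"posat-derived rate {c.derived} is non-positive"
                )
            out = out.updated(**{c.derived: k_close})
    for c in scheme.constraints:
        if c.kind != "detailed_balance":
            continue
        cyc = c.cycle
        m = len(cyc)
        dz = scheme.cycle_charge(cyc, None)
        if dz is not None and abs(dz) > 1e-9:
            raise UnbalancedCycleError(
                f"cycle {cyc} has nonzero net step charge; microscopic "
                "reversibility cannot hold at all voltages"
            )
        fwd_prod = 1.0
        bwd_prod = 1.0
        derived_side = None   # (+1 in forward product, -1 in backward)
        for i in range(m):
            a, b = cyc[i], cyc[(i + 1) % m]
            t, orient = scheme.transition_between(a, b)
            along = t.kf if orient > 0 else t.kb
            against = t.kb if orient > 0 else t.kf
            stoich_along = t.stoich_f if orient > 0 else t.stoich_b
            stoich_against = t.stoich_b if orient > 0 else t.stoich_f
            if along == c.derived:
                derived_side = (+1, stoich_along)
            else:
                fwd_prod *= out[along] * stoich_along
            if against == c.derived:
                derived_side = (-1, stoich_against)
            else:
                bwd_prod *= out[against] * stoich_against
        if derived_side is None:
            raise SchemeError(
                f"derived rate {c.derived!r} is not a rate of cycle {cyc}"
            )
        side, stoich = derived_side
        value = (bwd_prod / fwd_prod) if side > 0 else (fwd_prod / bwd_prod)
        value /= stoich
        if not value > 0 or not math.isfinite(value):
            raise InfeasibleConstraintError(
                f"detailed-balance-derived rate {c.derived} = {value} is infeasible"
            )
        out = out.updated(**{c.derived: value})
    # completeness check
    for name in scheme.parameter_names():
        out[name]
    return out


def cycle_rate_product_ratio(
    scheme: KineticScheme, cycle: tuple[str, ...], params: ParameterSet, V: float = 0.0
) -> float:
    """Clockwise / counter-clockwise rate product around ``cycle`` at V.

    Equals 1 for every voltage when microscopic reversibility holds.
    """
    fwd = 1.0
    bwd = 1.0
    m = len(cycle)
    for i in range(m):
        a, b = cycle[i], cycle[(i + 1) % m]
        t, orient = scheme.transition_between(a, b)
        kf, kb = transition_rates(scheme, t, params, V)
        along, against = (kf, kb) if orient > 0 else (kb, kf)
        fwd *= along
        bwd *= against
    return fwd / bwd


def charge_potential(scheme: KineticScheme, params: ParameterSet) -> np.ndarray:
    """Per-state charge coordinate w (elementary charges).

    w is the cumulative gating charge moved in reaching each state from the
    first state along any path; it is path-independent because step charges
    cancel around every cycle.  Total charge moved between two occupancy
    vectors p0, p1 is (p1 - p0) . w, the exact oracle for integrated gating
    currents.
    """
    w = {scheme.state_names[0]: 0.0}
    g = nx.Graph()
    g.add_edges_from((t.from_state, t.to_state) for t in scheme.transitions)
    for a, b in nx.bfs_edges(g, scheme.state_names[0]):
        t, orient = scheme.transition_between(a, b)
        z = params[t.charge] if t.charge is not None else 0.0
        w[b] = w[a] + orient * z
    return np.array([w[s] for s in scheme.state_names])
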