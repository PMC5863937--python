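"""Ready-made gating schemes for the HCN2 model competition.

Ships the two selected two-step models (``1n`` for the cAMP-free channel,
``1a`` for the cAMP-saturated channel, which adds a voltage-dependent
buffer state C1* off the activation pathway), a 10-state allosteric MWC
scheme with four voltage sensors, and a coupled-dimer (CD) scheme in which
the channel conducts only when both dimers are flipped.

Both two-step models are 2x3 rectangles: a closed row C0-C1-C2 and an open
row O0-O1-O2 connected by voltage-independent closed-open isomerizations at
the ends (C0-O0, C2-O2).  The horizontal steps carry the gating charges z1
(first step) and z2 (second step) in both rows; activation runs along the
closed row and deactivation along the open row.  Microscopic reversibility
derives k6 (O0->C0) from the ring and the saturating open probability
P_o,sat pins k8 = k7*(1-P_o,sat)/P_o,sat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .schemes import (
    ConstraintSpec,
    KineticScheme,
    ParameterSet,
    StateSpec,
    TransitionSpec,
    apply_constraints,
)

#: Saturating open probability of the final closed-open isomerization.
P_O_SAT = {"no_cAMP": 0.71, "cAMP": 0.99}

#: Globally fitted zero-voltage rate constants (s^-1) and gating charges
#: (elementary charges) of model 1n, cAMP-free condition.
PARAMS_1N = {
    "k1": 1.60e-1,
    "k2": 5.01e1,
    "z1": 0.79,
    "k3": 8.12e-8,
    "k4": 3.32e6,
    "z2": 7.31,
    "k5": 1.77e-2,
    "k7": 3.11,
    "k9": 1.30e-3,
    "k10": 2.35e1,
    "k11": 5.11e-5,
    "k12": 8.93e3,
}

#: As PARAMS_1N but for model 1a at saturating (10 uM) cAMP; adds the
#: C1<->C1* buffer step (k13/k14, charge zc).
PARAMS_1A = {
    "k1": 3.24,
    "k2": 1.21e2,
    "z1": 0.78,
    "k3": 1.70e-3,
    "k4": 9.88e4,
    "z2": 4.34,
    "k5": 2.12e-1,
    "k7": 4.45,
    "k9": 3.10,
    "k10": 2.68e1,
    "k11": 4.92e-2,
    "k12": 6.96e2,
    "k13": 1.85e-1,
    "k14": 1.84,
    "zc": 1.03,
}

#: Per-parameter standard errors (% of value) from the global fits;
#: None marks a parameter reported as not determined (se > 60%).
SE_PERCENT_1N = {
    "k1": 7, "k2": 13, "z1": 3, "k3": 22, "k4": 13, "z2": 1, "k5": 56,
    "k7": 3, "k9": None, "k10": 2, "k11": None, "k12": 6,
}


@dataclass
class CatalogEntry:
    """A pre-built scheme plus its model-competition bookkeeping flags:
    st (stoichiometric factors used), ze (one shared z for all steps),
    f (allosteric factor used)."""

    scheme: KineticScheme
    flags: dict = field(default_factory=dict)
    n_free_params: int = 0
    params: ParameterSet | None = None


def _two_step_core(name: str, p_open_sat: float) -> tuple[list, list, list]:
    states = [
        StateSpec("C0"), StateSpec("C1"), StateSpec("C2"),
        StateSpec("O0", conducting=True),
        StateSpec("O1", conducting=True),
        StateSpec("O2", conducting=True),
    ]
    transitions = [
        TransitionSpec("C0", "C1", "k1", "k2", charge="z1"),
        TransitionSpec("C1", "C2", "k3", "k4", charge="z2"),
        TransitionSpec("C0", "O0", "k5", "k6"),
        TransitionSpec("C2", "O2", "k7", "k8"),
        TransitionSpec("O0", "O1", "k9", "k10", charge="z1"),
        TransitionSpec("O1", "O2", "k11", "k12", charge="z2"),
    ]
    constraints = [
        ConstraintSpec("posat", derived="k8", open_rate="k7", p_open_sat=p_open_sat),
        ConstraintSpec(
            "detailed_balance",
            cycle=("C0", "C1", "C2", "O2", "O1", "O0"),
            derived="k6",
        ),
    ]
    return states, transitions, constraints


def build_model_1n(p_open_sat: float = P_O_SAT["no_cAMP"]) -> KineticScheme:
    """Two-step model of the cAMP-free channel: 6 states, 6 reversible
    steps, k6 cycle-derived and k8 pinned by P_o,sat."""
    states, transitions, constraints = _two_step_core("1n", p_open_sat)
    return KineticScheme("1n", states, transitions, constraints)


def build_model_1a(p_open_sat: float = P_O_SAT["cAMP"]) -> KineticScheme:
    """Model 1n plus a voltage-dependent buffer state C1* reachable only
    from C1 (step k13/k14, charge zc); 7 states."""
    states, transitions, constraints = _two_step_core("1a", p_open_sat)
    states = states + [StateSpec("C1star")]
    transitions = transitions + [
        TransitionSpec("C1", "C1star", "k13", "k14", charge="zc"),
    ]
    return KineticScheme("1a", states, transitions, constraints)


def build_model_mwc(n_sensors: int = 4) -> KineticScheme:
    """Allosteric MWC scheme: n_sensors+1 closed and open states.

    Sensor step j (1-based) carries stoichiometric factor (n-j+1) forward
    and j backward; all sensor steps share one gating charge ``zs`` and one
    rate pair (``a0``, ``b0``).  The concerted closed-open isomerization
    (``kco``/``koc``) at sensor level j has its equilibrium scaled by the
    allosteric factor f^j, implemented as a symmetric sqrt(f) split on the
    open-row sensor rates so every rung cycle obeys detailed balance by
    construction.  f enters as a fixed numeric factor of the build.
    """
    if not 1 <= n_sensors <= 4:
        raise ValueError(f"n_sensors must be in 1..4, got {n_sensors}")
    return _build_mwc(n_sensors, f=DEFAULT_MWC_F)


DEFAULT_MWC_F = 3.0


def _build_mwc(n_sensors: int, f: float) -> KineticScheme:
    n = n_sensors
    sf = math.sqrt(f)
    states = [StateSpec(f"C{j}") for j in range(n + 1)] + [
        StateSpec(f"O{j}", conducting=True) for j in range(n + 1)
    ]
    transitions = []
    for j in range(1, n + 1):
        transitions.append(
            TransitionSpec(f"C{j-1}", f"C{j}", "a0", "b0", charge="zs",
                           stoich_f=float(n - j + 1), stoich_b=float(j))
        )
        transitions.append(
            TransitionSpec(f"O{j-1}", f"O{j}", "a0", "b0", charge="zs",
                           stoich_f=float(n - j + 1) * sf, stoich_b=float(j) / sf)
        )
    # closed-open isomerization at sensor level j has equilibrium L * f^j;
    # the sqrt(f) split on open-row sensor steps plus the f^(j/2) scaling
    # here closes detailed balance around every rung cycle by construction
    for j in range(0, n + 1):
        transitions.append(
            TransitionSpec(f"C{j}", f"O{j}", "kco", "koc",
                           stoich_f=sf ** j, stoich_b=sf ** (-j))
        )
    return KineticScheme(f"mwc{2 * (n + 1)}", states, transitions, [])


def build_model_cd() -> KineticScheme:
    """Coupled-dimer scheme: two identical dimers, each resting (r),
    activated (a) or flipped (f); the channel conducts only with both
    dimers flipped.  Composite states are unordered pairs, with the usual
    combinatorial factor 2 where either dimer may move.  The r<->a step is
    voltage dependent (charge ``zd``), the a<->f flip is not.
    """
    states = [
        StateSpec("rr"), StateSpec("ra"), StateSpec("rf"),
        StateSpec("aa"), StateSpec("af"),
        StateSpec("ff", conducting=True),
    ]
    transitions = [
        TransitionSpec("rr", "ra", "kra", "kar", charge="zd", stoich_f=2.0),
        TransitionSpec("ra", "aa", "kra", "kar", charge="zd", stoich_b=2.0),
        TransitionSpec("ra", "rf", "kaf", "kfa"),
        TransitionSpec("aa", "af", "kaf", "kfa", stoich_f=2.0),
        TransitionSpec("rf", "af", "kra", "kar", charge="zd"),
        TransitionSpec("af", "ff", "kaf", "kfa", stoich_b=2.0),
    ]
    return KineticScheme("cd", states, transitions, [])


#: Plausible default parameters for the MWC and CD demonstration schemes
#: (the study conditions fix only the two-step models' values).
DEFAULT_MWC_PARAMS = {"a0": 0.8, "b0": 80.0, "zs": 1.6, "kco": 0.5, "koc": 5.0}
DEFAULT_CD_PARAMS = {"kra": 1.0, "kar": 100.0, "zd": 2.0, "kaf": 5.0, "kfa": 1.0}


def table_params(name: str) -> ParameterSet:
    """Published parameter values for a catalog model (underived: the
    constrained rates k6/k8 resp. koc_j are filled by apply_constraints)."""
    if name == "1n":
        return ParameterSet(dict(PARAMS_1N))
    if name == "1a":
        return ParameterSet(dict(PARAMS_1A))
    if name.startswith("mwc"):
        return ParameterSet(dict(DEFAULT_MWC_PARAMS))
    if name == "cd":
        return ParameterSet(dict(DEFAULT_CD_PARAMS))
    raise KeyError(f"no parameter table for model {name!r}")


def catalog_entry(name: str) -> CatalogEntry:
    """Catalog lookup by name: '1n', '1a', 'mwc10', 'cd'."""
    if name == "1n":
        scheme = build_model_1n()
        flags = {"st": False, "ze": False, "f": False}
    elif name == "1a":
        scheme = build_model_1a()
        flags = {"st": False, "ze": False, "f": False}
    elif name == "mwc10":
        scheme = build_model_mwc(4)
        flags = {"st": True, "ze": True, "f": True}
    elif name == "cd":
        scheme = build_model_cd()
        flags = {"st": True, "ze": True, "f": False}
    else:
        raise KeyError(f"unknown catalog model {name!r}; available: 1n, 1a, mwc10, cd")
    params = table_params(name)
    return CatalogEntry(
        scheme=scheme,
        flags=flags,
        n_free_params=len(scheme.free_parameter_names()),
        params=params,
    )


def load_model(name: str) -> tuple[KineticScheme, ParameterSet]:
    """Scheme plus fully derived (constraint-applied) published parameters."""
    entry = catalog_entry(name)
    return entry.scheme, apply_constraints(entry.scheme, entry.params)
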