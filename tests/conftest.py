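import numpy as np
import pytest

from hcngating import (
    KineticScheme,
    ParameterSet,
    StateSpec,
    TransitionSpec,
    load_model,
)


@pytest.fixture(scope="session")
def model_1n():
    """Two-step model of the cAMP-free channel with published parameters
    (constraints applied)."""
    return load_model("1n")


@pytest.fixture(scope="session")
def model_1a():
    """Buffer-state model of the cAMP-saturated channel with published
    parameters (constraints applied)."""
    return load_model("1a")


@pytest.fixture
def two_state():
    """Minimal closed<->open toy scheme."""
    scheme = KineticScheme(
        "toy2",
        [StateSpec("C"), StateSpec("O", conducting=True)],
        [TransitionSpec("C", "O", "kf", "kb")],
    )
    params = ParameterSet({"kf": 1.0, "kb": 1.0})
    return scheme, params


def ring_scheme(n: int, rates=None, charge=False):
    """n-state ring with one detailed-balance-derived rate (the backward
    rate of the closing edge)."""
    from hcngating import ConstraintSpec

    states = [StateSpec(f"S{i}", conducting=(i == n - 1)) for i in range(n)]
    transitions = []
    names = {}
    for i in range(n):
        j = (i + 1) % n
        kf, kb = f"f{i}", f"b{i}"
        transitions.append(
            TransitionSpec(f"S{i}", f"S{j}", kf, kb,
                           charge="zr" if charge else None,
                           partition=0.5)
        )
        names[kf] = names[kb] = True
    constraints = [
        ConstraintSpec(
            "detailed_balance",
            cycle=tuple(f"S{i}" for i in range(n)),
            derived=f"b{n-1}",
        )
    ]
    scheme = KineticScheme(f"ring{n}", states, transitions, constraints)
    if rates is None:
        rates = {k: 1.0 for t in transitions for k in (t.kf, t.kb)}
    if charge:
        rates = dict(rates)
        rates["zr"] = 0.0  # ring with shared charge would not cancel unless 0
    return scheme, ParameterSet(rates)
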