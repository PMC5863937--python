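"""Global least-squares fitting of gating schemes to P_o trace sets.

All traces of a set (27 double-pulse protocols in the study design) are
fitted simultaneously: rate constants are optimized in log-space, gating
charges linearly, with constraint-derived rates (detailed balance,
P_o,sat) recomputed from the candidate parameters at every evaluation so
the constraints hold by construction rather than by penalty.

Goodness of fit is reported two ways: RSS, the plain residual sum of
squares over all traces and samples, and MSE*, the sigma-normalized mean
square error (1/N) sum_i (r_i / sigma_i)^2 — approximately 1 when the
model is correct and the per-point sigmas are honest.  Parameter standard
errors come from the curvature of the weighted least-squares problem at
the optimum; a parameter with se > 60% of its value is flagged "not
determined" (n.d.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .schemes import KineticScheme, ParameterSet, apply_constraints, charge_potential
from .simulate import Propagator, VoltageProtocol, open_probability, simulate_protocol

#: weights are capped by flooring sigma here, to avoid near-infinite
#: weights on noise-free synthetic points
SIGMA_FLOOR = 1e-3

#: n.d. threshold: standard error above this percentage of the value
ND_SE_PERCENT = 60.0


class FitError(RuntimeError):
    """All optimizer starts failed; carries the per-start log."""


@dataclass
class Trace:
    """One averaged P_o time course with per-point uncertainty."""

    protocol: VoltageProtocol
    times: np.ndarray
    po: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("trace sigma must be positive")
        if self.times[-1] > self.protocol.total_duration + 1e-9:
            raise ValueError("trace samples extend beyond the protocol")


@dataclass
class TraceSet:
    traces: list[Trace]
    condition: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return sum(len(t.times) for t in self.traces)

    def fingerprint(self) -> tuple:
        """Cheap identity used to refuse cross-traceset model rankings."""
        return (
            self.condition,
            len(self.traces),
            self.n_points,
            round(float(sum(t.times[-1] for t in self.traces)), 9),
        )


@dataclass
class FitSpec:
    """What to fit and how.

    ``free_rates`` are optimized as log10-free positive rates,
    ``free_charges`` linearly in [0, charge_max].  ``base_params`` supplies
    every non-free value (and the start for free ones unless ``init``
    overrides).  ``n_starts`` > 1 adds seeded random multistarts drawn
    log-uniformly (rates) / uniformly (charges) within the start ranges.
    """

    scheme: KineticScheme
    base_params: ParameterSet
    free_rates: list[str] = field(default_factory=list)
    free_charges: list[str] = field(default_factory=list)
    init: dict = field(default_factory=dict)
    n_starts: int = 32
    seed: int = 0
    rate_bounds: tuple[float, float] = (1e-9, 1e9)
    charge_max: float = 12.0
    start_rate_range: tuple[float, float] = (1e-4, 1e4)
    xtol: float = 1e-12
    ftol: float = 1e-12

    def __post_init__(self):
        known = set(self.scheme.parameter_names())
        derived = set(self.scheme.derived_names())
        for name in self.free_rates + self.free_charges:
            if name not in known:
                raise ValueError(f"free parameter {name!r} not in scheme")
            if name in derived:
                raise ValueError(f"{name!r} is constraint-derived and cannot be free")

    @property
    def free_names(self) -> list[str]:
        return list(self.free_rates) + list(self.free_charges)

    # -- vector encoding ----------------------------------------------------

    def encode(self, values: dict) -> np.ndarray:
        x = [math.log(values[n]) for n in self.free_rates]
        x += [float(values[n]) for n in self.free_charges]
        return np.array(x)

    def decode(self, x: np.ndarray) -> dict:
        nr = len(self.free_rates)
        out = {n: math.exp(x[i]) for i, n in enumerate(self.free_rates)}
        out.update({n: float(x[nr + i]) for i, n in enumerate(self.free_charges)})
        return out

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = [math.log(self.rate_bounds[0])] * len(self.free_rates)
        hi = [math.log(self.rate_bounds[1])] * len(self.free_rates)
        lo += [0.0] * len(self.free_charges)
        hi += [self.charge_max] * len(self.free_charges)
        return np.array(lo), np.array(hi)


@dataclass
class FitResult:
    """Optimized parameters and diagnostics for one model on one traceset."""

    scheme: KineticScheme
    params: ParameterSet                # constraint-applied, at the optimum
    free_values: dict
    rss: float
    mse_star: float
    se_percent: dict
    nd: dict
    n_free: int
    nd_count: int
    n_points: int
    seed: int
    traceset_key: tuple
    start_log: list = field(default_factory=list)
    success: bool = True

    @property
    def sumz(self) -> float:
        """Total gating charge: range of the per-state charge potential
        (for the two-step models this is z1 + z2)."""
        w = charge_potential(self.scheme, self.params)
        return float(w.max() - w.min())


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def model_po(
    traceset: TraceSet, scheme: KineticScheme, params: ParameterSet
) -> list[np.ndarray]:
    """Model P_o at each trace's sample times (one shared propagator so
    per-voltage generator decompositions are reused across traces)."""
    prop = Propagator(scheme, params)
    out = []
    for tr in traceset.traces:
        traj = simulate_protocol(scheme, params, tr.protocol, propagator=prop)
        po = open_probability(traj)
        out.append(np.interp(tr.times, traj.times, po))
    return out


def objective(
    traceset: TraceSet, scheme: KineticScheme, params: ParameterSet
) -> tuple[float, float]:
    """(RSS, MSE*) of constraint-applied ``params`` against the traceset."""
    mod = model_po(traceset, scheme, params)
    rss = 0.0
    chi2 = 0.0
    n = 0
    for tr, m in zip(traceset.traces, mod):
        r = m - tr.po
        rss += float(r @ r)
        w = np.maximum(tr.sigma, SIGMA_FLOOR)
        chi2 += float(((r / w) ** 2).sum())
        n += len(r)
    return rss, chi2 / n


def _weighted_residuals(
    x: np.ndarray, spec: FitSpec, traceset: TraceSet
) -> np.ndarray:
    params = spec.base_params.updated(**spec.decode(x))
    try:
        full = apply_constraints(spec.scheme, params)
        mod = model_po(traceset, spec.scheme, full)
    except (ValueError, np.linalg.LinAlgError):
        # infeasible candidate: large penalty keeps the optimizer moving
        return np.full(traceset.n_points, 1e3)
    parts = [
        (m - tr.po) / np.maximum(tr.sigma, SIGMA_FLOOR)
        for tr, m in zip(traceset.traces, mod)
    ]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def _polished_least_squares(x0, spec, traceset, lo, hi, max_restarts: int = 10):
    """Trust-region least squares with restart polishing.

    The global objective has long curved valleys (sloppy log-rate
    combinations); a single trust-region run can stall on them, so the
    solver is restarted from its own solution until the cost stops
    improving.  3-point difference Jacobians keep the gradient accurate
    enough for the final restarts to actually terminate at the optimum.
    """
    x = x0
    sol = None
    prev = None
    for _ in range(max_restarts):
        sol = least_squares(
            _weighted_residuals, x, args=(spec, traceset),
            bounds=(lo, hi), method="trf", jac="3-point",
            xtol=spec.xtol, ftol=spec.ftol, gtol=1e-14,
        )
        x = sol.x
        if prev is not None and prev - sol.cost < 1e-9 * (1.0 + sol.cost):
            break
        prev = sol.cost
    return sol


def global_fit(traceset: TraceSet, spec: FitSpec) -> FitResult:
    """Multistart local least-squares over the free parameters.

    Start 0 is the base/init value; further starts are seeded random draws.
    Returns the best-of-starts with parameter errors and n.d. flags;
    bit-reproducible for a fixed seed and tolerance set.
    """
    if not traceset.traces:
        raise ValueError("traceset is empty")
    names = spec.free_names
    if not names:
        full = apply_constraints(spec.scheme, spec.base_params)
        rss, mse = objective(traceset, spec.scheme, full)
        return FitResult(
            scheme=spec.scheme, params=full, free_values={}, rss=rss,
            mse_star=mse, se_percent={}, nd={}, n_free=0, nd_count=0,
            n_points=traceset.n_points, seed=spec.seed,
            traceset_key=traceset.fingerprint(),
        )

    start_values = {n: spec.init.get(n, spec.base_params[n]) for n in names}
    x0 = spec.encode(start_values)
    lo, hi = spec.bounds()
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    lr0, lr1 = math.log(spec.start_rate_range[0]), math.log(spec.start_rate_range[1])
    for _ in range(max(0, spec.n_starts - 1)):
        xs = np.empty_like(x0)
        nr = len(spec.free_rates)
        xs[:nr] = rng.uniform(lr0, lr1, nr)
        xs[nr:] = rng.uniform(0.0, spec.charge_max, len(spec.free_charges))
        starts.append(np.clip(xs, lo, hi))

    best = None
    log = []
    for i, xs in enumerate(starts):
        try:
            sol = _polished_least_squares(xs, spec, traceset, lo, hi)
            log.append({"start": i, "cost": float(sol.cost), "status": sol.status})
            if best is None or sol.cost < best.cost:
                best = sol
        except Exception as err:  # noqa: BLE001 - per-start failures are logged
            log.append({"start": i, "error": repr(err)})
    if best is None:
        raise FitError(f"all {len(starts)} starts failed: {log}")

    free_values = spec.decode(best.x)
    full = apply_constraints(spec.scheme, spec.base_params.updated(**free_values))
    rss, mse = objective(traceset, spec.scheme, full)
    # errors from an unscaled central-difference Jacobian: the Jacobian
    # reported by bounded trust-region solvers carries the Coleman-Li
    # scaling and would bias the covariance
    jac = _fd_jacobian(best.x, spec, traceset)
    se_percent, nd = _errors_from_jacobian(jac, best.fun, spec, best.x)
    return FitResult(
        scheme=spec.scheme, params=full, free_values=free_values,
        rss=rss, mse_star=mse, se_percent=se_percent, nd=nd,
        n_free=len(names), nd_count=sum(nd.values()),
        n_points=traceset.n_points, seed=spec.seed,
        traceset_key=traceset.fingerprint(), start_log=log,
    )


def _errors_from_jacobian(
    jac: np.ndarray, fun: np.ndarray, spec: FitSpec, x: np.ndarray
) -> tuple[dict, dict]:
    """Asymptotic standard errors from the weighted-residual Jacobian.

    cov = (J^T J)^-1 * s^2 with s^2 the reduced chi-square; singular
    curvature directions get infinite errors (n.d.).
    """
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(fun @ fun) / dof
    jtj = jac.T @ jac
    # pseudo-inverse so rank-deficient problems degrade to n.d. flags
    evals, evecs = np.linalg.eigh(jtj)
    tol = max(evals.max(), 0.0) * 1e-12
    inv = np.where(evals > tol, 1.0 / np.maximum(evals, tol), np.inf)
    var = np.einsum("ij,j,ij->i", evecs, inv, evecs) * s2
    se_x = np.sqrt(np.abs(var))
    se_percent = {}
    nd = {}
    nr = len(spec.free_rates)
    for i, name in enumerate(spec.free_names):
        if i < nr:
            # log-space error: se of ln k, as a fraction of the value
            pct = 100.0 * se_x[i]
        else:
            val = abs(x[i])
            pct = 100.0 * se_x[i] / val if val > 0 else math.inf
        se_percent[name] = float(pct)
        nd[name] = bool(pct > ND_SE_PERCENT)
    return se_percent, nd


def parameter_errors(
    result: FitResult, traceset: TraceSet, spec: FitSpec, rel_step: float = 1e-6
) -> tuple[dict, dict]:
    """Recompute se% and n.d. flags by finite-difference curvature at the
    optimum — an optimizer-independent route to the same asymptotic errors
    stored on the FitResult."""
    x = spec.encode({n: result.free_values[n] for n in spec.free_names})
    f0 = _weighted_residuals(x, spec, traceset)
    jac = _fd_jacobian(x, spec, traceset, rel_step)
    return _errors_from_jacobian(jac, f0, spec, x)


def _fd_jacobian(
    x: np.ndarray, spec: FitSpec, traceset: TraceSet, rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of the weighted residuals."""
    cols = []
    for i in range(len(x)):
        dx = np.zeros_like(x)
        dx[i] = max(abs(x[i]) * rel_step, rel_step)
        f_plus = _weighted_residuals(x + dx, spec, traceset)
        f_minus = _weighted_residuals(x - dx, spec, traceset)
        cols.append((f_plus - f_minus) / (2.0 * dx[i]))
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# model ranking
# ---------------------------------------------------------------------------

def rank_models(
    fits: list[FitResult],
    names: list[str] | None = None,
    flags: list[dict] | None = None,
) -> pd.DataFrame:
    """Model-competition table sorted by MSE* (ties: fewer free parameters,
    then fewer n.d. parameters).  All fits must be on the same traceset."""
    if not fits:
        raise ValueError("no fits to rank")
    keys = {f.traceset_key for f in fits}
    if len(keys) > 1:
        raise ValueError(f"fits span different tracesets: {keys}")
    rows = []
    for i, f in enumerate(fits):
        fl = flags[i] if flags else {}
        rows.append(
            {
                "model": names[i] if names else f.scheme.name,
                "st": fl.get("st", False),
                "ze": fl.get("ze", False),
                "f": fl.get("f", False),
                "sumz": f.sumz,
                "p": f.n_free,
                "nd_p": f.nd_count,
                "RSS": f.rss,
                "MSE*": f.mse_star,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["MSE*", "p", "nd_p"], kind="mergesort").reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
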