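"""Objective bookkeeping, global fits, parameter errors and model ranking."""

import numpy as np
import pytest

from hcngating import (
    FitSpec,
    KineticScheme,
    NoiseModel,
    ParameterSet,
    StateSpec,
    Trace,
    TraceSet,
    TransitionSpec,
    VoltageProtocol,
    generate_traceset,
    global_fit,
    load_model,
    make_protocols,
    objective,
    parameter_errors,
    rank_models,
)
from hcngating.fitting import FitError


@pytest.fixture(scope="module")
def small_protocols():
    """Reduced protocol grid (one per activation voltage) for quick fits."""
    full = make_protocols("no_cAMP", sample_dt=1e-2)
    return [full[i] for i in (0, 10, 20)]


@pytest.fixture(scope="module")
def clean_traceset(small_protocols):
    scheme, truth = load_model("1n")
    return generate_traceset(
        scheme, truth, small_protocols, NoiseModel.zero(), seed=0, condition="no_cAMP"
    )


class TestObjective:
    def test_zero_rss_on_generating_parameters(self, model_1n, clean_traceset):
        scheme, truth = model_1n
        rss, mse = objective(clean_traceset, scheme, truth)
        assert rss == pytest.approx(0.0, abs=1e-16)
        assert mse == pytest.approx(0.0, abs=1e-16)

    def test_mse_star_near_one_for_matched_noise(self, model_1n, small_protocols):
        """With Gaussian noise at the declared sigma and the generating
        parameters, the normalized mean square error is ~1 (chi-square
        expectation, 3/sqrt(N) band)."""
        scheme, truth = model_1n
        ts = generate_traceset(
            scheme, truth, small_protocols,
            NoiseModel(a=0.01, b=0.0, patch_jitter=0.0),
            n_patches_range=(1, 1), seed=3, condition="no_cAMP",
        )
        _, mse = objective(ts, scheme, truth)
        assert mse == pytest.approx(1.0, abs=3.0 / np.sqrt(ts.n_points))

    def test_invariant_under_trace_reordering(self, model_1n, small_protocols):
        scheme, truth = model_1n
        ts = generate_traceset(
            scheme, truth, small_protocols, NoiseModel(), seed=4, condition="no_cAMP"
        )
        shuffled = TraceSet(list(reversed(ts.traces)), ts.condition, ts.meta)
        assert objective(ts, scheme, truth) == objective(shuffled, scheme, truth)


class TestGlobalFit:
    def test_zero_free_parameters_returns_fixed_objective(self, model_1n, clean_traceset):
        scheme, truth = model_1n
        spec = FitSpec(scheme=scheme, base_params=truth)
        res = global_fit(clean_traceset, spec)
        rss, mse = objective(clean_traceset, scheme, truth)
        assert (res.rss, res.mse_star) == (rss, mse)
        assert res.n_free == 0

    def test_recovers_perturbed_rates_on_clean_data(self, model_1n, clean_traceset):
        """Fitting two informative rates on noise-free data drives RSS to
        ~0 and returns the generating values."""
        scheme, truth = model_1n
        init = {"k1": truth["k1"] * 2.0, "k7": truth["k7"] * 0.5}
        spec = FitSpec(
            scheme=scheme, base_params=truth, free_rates=["k1", "k7"],
            init=init, n_starts=1, seed=0,
        )
        res = global_fit(clean_traceset, spec)
        assert res.free_values["k1"] == pytest.approx(truth["k1"], rel=1e-4)
        assert res.free_values["k7"] == pytest.approx(truth["k7"], rel=1e-4)
        assert res.rss < 1e-8

    def test_reproducible_for_fixed_seed(self, model_1n, clean_traceset):
        scheme, truth = model_1n
        def run():
            spec = FitSpec(
                scheme=scheme, base_params=truth, free_rates=["k1"],
                init={"k1": 1.0}, n_starts=3, seed=7,
            )
            return global_fit(clean_traceset, spec)
        r1, r2 = run(), run()
        assert r1.free_values == r2.free_values
        assert r1.rss == r2.rss

    def test_free_parameter_validation(self, model_1n):
        scheme, truth = model_1n
        with pytest.raises(ValueError, match="not in scheme"):
            FitSpec(scheme=scheme, base_params=truth, free_rates=["nope"])
        with pytest.raises(ValueError, match="derived"):
            FitSpec(scheme=scheme, base_params=truth, free_rates=["k6"])

    def test_wrong_charges_fit_worse_than_refit(self, model_1a):
        """Data generated with the cAMP-condition charges cannot be
        described by clamping the charges to the cAMP-free values, even
        with all rates refitted: MSE* stays far above the matched fit."""
        scheme, truth = model_1a
        protocols = [make_protocols("cAMP", sample_dt=1e-2)[i] for i in (0, 10, 20)]
        ts = generate_traceset(
            scheme, truth, protocols, NoiseModel(a=0.01, b=0.0, patch_jitter=0.0),
            n_patches_range=(1, 1), seed=5, condition="cAMP",
        )
        free = ["k1", "k2", "k3", "k4"]
        matched = global_fit(
            ts,
            FitSpec(scheme=scheme, base_params=truth, free_rates=free,
                    init={n: truth[n] * 1.5 for n in free}, n_starts=1, seed=0),
        )
        clamped_base = truth.updated(z1=0.79, z2=7.31)
        clamped = global_fit(
            ts,
            FitSpec(scheme=scheme, base_params=clamped_base, free_rates=free,
                    init={n: truth[n] for n in free}, n_starts=1, seed=0),
        )
        assert clamped.mse_star > 5.0 * matched.mse_star


class TestParameterErrors:
    def test_vanishing_noise_gives_vanishing_se(self, model_1n, small_protocols):
        """se% shrinks with the noise level for identifiable parameters."""
        scheme, truth = model_1n
        ses = []
        for sigma in (0.02, 0.002):
            ts = generate_traceset(
                scheme, truth, small_protocols,
                NoiseModel(a=sigma, b=0.0, patch_jitter=0.0),
                n_patches_range=(1, 1), seed=6, condition="no_cAMP",
            )
            spec = FitSpec(
                scheme=scheme, base_params=truth, free_rates=["k7"],
                init={"k7": truth["k7"]}, n_starts=1, seed=0,
            )
            res = global_fit(ts, spec)
            ses.append(res.se_percent["k7"])
        assert ses[1] < 0.2 * ses[0]
        assert ses[1] < 1.0

    def test_finite_difference_errors_match_stored(self, model_1n, small_protocols):
        scheme, truth = model_1n
        ts = generate_traceset(
            scheme, truth, small_protocols,
            NoiseModel(a=0.01, b=0.0, patch_jitter=0.0),
            n_patches_range=(1, 1), seed=8, condition="no_cAMP",
        )
        spec = FitSpec(
            scheme=scheme, base_params=truth, free_rates=["k1", "k7"],
            init={"k1": truth["k1"], "k7": truth["k7"]}, n_starts=1, seed=0,
        )
        res = global_fit(ts, spec)
        se_fd, nd_fd = parameter_errors(res, ts, spec)
        for n in ("k1", "k7"):
            assert se_fd[n] == pytest.approx(res.se_percent[n], rel=0.05)
            assert nd_fd[n] == res.nd[n]

    def test_curvature_se_matches_bootstrap_on_toy(self):
        """On a two-parameter relaxation toy, curvature-based se agrees
        with a parametric bootstrap over noise realizations within a
        factor of 2."""
        scheme = KineticScheme(
            "toy2",
            [StateSpec("C"), StateSpec("O", conducting=True)],
            [TransitionSpec("C", "O", "kf", "kb", charge="z")],
        )
        truth = ParameterSet({"kf": 2.0, "kb": 3.0, "z": 1.0})
        # holding at +300 mV pins the channel closed; the step relaxes it
        proto = VoltageProtocol(holding=300.0, segments=[(-50.0, 2.0)], sample_dt=1e-2)
        from hcngating import open_probability, simulate_protocol

        traj = simulate_protocol(scheme, truth, proto)
        clean = open_probability(traj)
        sigma = 0.02
        rng = np.random.default_rng(0)

        def fit_once(po):
            ts = TraceSet(
                [Trace(proto, traj.times, po, np.full_like(po, sigma))], "toy"
            )
            spec = FitSpec(
                scheme=scheme, base_params=truth, free_rates=["kf", "kb"],
                init={"kf": 2.0, "kb": 3.0}, n_starts=1, seed=0,
            )
            return global_fit(ts, spec)

        ref = fit_once(clean + sigma * rng.standard_normal(len(clean)))
        boots = [
            fit_once(clean + sigma * rng.standard_normal(len(clean)))
            for _ in range(30)
        ]
        for name in ("kf", "kb"):
            emp = np.std([np.log(b.free_values[name]) for b in boots]) * 100
            assert ref.se_percent[name] == pytest.approx(emp, rel=1.0)
            assert emp / 2 < ref.se_percent[name] < emp * 2


class TestRankModels:
    def test_single_fit_table(self, model_1n, clean_traceset):
        scheme, truth = model_1n
        res = global_fit(clean_traceset, FitSpec(scheme=scheme, base_params=truth))
        table = rank_models([res], names=["1n"])
        assert len(table) == 1
        assert table.loc[1, "model"] == "1n"

    def test_sumz_for_model_1n(self, model_1n, clean_traceset):
        scheme, truth = model_1n
        res = global_fit(clean_traceset, FitSpec(scheme=scheme, base_params=truth))
        assert res.sumz == pytest.approx(8.10, abs=1e-9)
        table = rank_models([res])
        assert table.loc[1, "sumz"] == pytest.approx(8.10)

    def test_generating_model_outranks_overconstrained_one(self, model_1n, small_protocols):
        """On synthetic two-step data, the generating two-step scheme beats
        a one-gating-step model in the MSE* ranking."""
        scheme, truth = model_1n
        ts = generate_traceset(
            scheme, truth, small_protocols,
            NoiseModel(a=0.01, b=0.0, patch_jitter=0.0),
            n_patches_range=(1, 1), seed=9, condition="no_cAMP",
        )
        fit_true = global_fit(ts, FitSpec(scheme=scheme, base_params=truth))

        from hcngating import ConstraintSpec

        one_step = KineticScheme(
            "one_step",
            [StateSpec("C0"), StateSpec("C1"), StateSpec("O1", conducting=True)],
            [
                TransitionSpec("C0", "C1", "k1", "k2", charge="z1"),
                TransitionSpec("C1", "O1", "k7", "k8"),
            ],
            [ConstraintSpec("posat", derived="k8", open_rate="k7", p_open_sat=0.71)],
        )
        base = ParameterSet({"k1": 0.2, "k2": 20.0, "z1": 6.0, "k7": 3.0})
        spec = FitSpec(
            scheme=one_step, base_params=base,
            free_rates=["k1", "k2", "k7"], free_charges=["z1"],
            n_starts=4, seed=1,
        )
        fit_one = global_fit(ts, spec)
        table = rank_models([fit_one, fit_true], names=["one_step", "1n"])
        assert table.loc[1, "model"] == "1n"
        assert table.loc[1, "MSE*"] < table.loc[2, "MSE*"]

    def test_mixed_tracesets_rejected(self, model_1n, small_protocols, clean_traceset):
        scheme, truth = model_1n
        other = generate_traceset(
            scheme, truth, small_protocols[:2], NoiseModel.zero(), seed=0
        )
        r1 = global_fit(clean_traceset, FitSpec(scheme=scheme, base_params=truth))
        r2 = global_fit(other, FitSpec(scheme=scheme, base_params=truth))
        with pytest.raises(ValueError, match="different tracesets"):
            rank_models([r1, r2])


def test_all_starts_failing_raises(model_1n, clean_traceset):
    scheme, truth = model_1n
    spec = FitSpec(
        scheme=scheme, base_params=truth, free_rates=["k1"], n_starts=1, seed=0
    )
    import hcngating.fitting as fitting

    orig = fitting._polished_least_squares
    fitting._polished_least_squares = lambda *a, **k: (_ for _ in ()).throw(RuntimeError("boom"))
    try:
        with pytest.raises(FitError):
            global_fit(clean_traceset, spec)
    finally:
        fitting._polished_least_squares = orig
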