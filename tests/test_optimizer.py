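import numpy as np
import pytest

from cstfp import (
    CstfpConfig,
    CstfpModel,
    ParameterSet,
    Trial,
    TrialSet,
    build_deflation_subspace,
    contiguous_candidates,
    fit,
    filter_peak_frequency,
    objective,
    update_b,
    update_h,
    update_w,
)
from cstfp.optimizer import DeflationSubspace
from cstfp.window_candidates import WindowCandidateSet
from helpers import objective_direct, random_trialset, small_fit_config


@pytest.fixture
def toy(rng):
    return random_trialset(rng, M=3, N=24, per_class=6, scale2=1.4)


class TestObjective:
    def test_matches_direct_recomputation(self, rng):
        trials = random_trialset(rng, M=2, N=8, per_class=2)
        w, h = rng.standard_normal(2), rng.standard_normal(2)
        b = np.array([1, 1, 0, 1, 1, 0, 1], dtype=float)
        p = ParameterSet(w, h, b)
        got = objective(trials, p, eps=0.3, c=1)
        want = objective_direct(trials, p.w, p.h, p.b, eps=0.3, c=1)
        assert got.total == pytest.approx(want, rel=1e-10)

    def test_symmetric_classes_give_half(self, rng):
        mats = [rng.standard_normal((2, 10)) for _ in range(3)]
        trials = TrialSet([Trial(m, 1) for m in mats] + [Trial(m, 2) for m in mats])
        p = ParameterSet(rng.standard_normal(2), rng.standard_normal(3), np.ones(8))
        assert objective(trials, p, eps=0.0).j_hat == pytest.approx(0.5, abs=1e-12)

    def test_zero_eps_drops_penalty(self, toy, rng):
        p = ParameterSet(rng.standard_normal(3), rng.standard_normal(4), np.ones(21))
        v = objective(toy, p, eps=0.0)
        assert v.penalty == 0.0 and v.total == v.j_hat

    def test_class_ratios_sum_to_one(self, toy, rng):
        p = ParameterSet(rng.standard_normal(3), rng.standard_normal(4), np.ones(21))
        j1 = objective(toy, p, eps=0.0, c=1).j_hat
        j2 = objective(toy, p, eps=0.0, c=2).j_hat
        assert j1 + j2 == pytest.approx(1.0, abs=1e-10)
        assert 0.0 <= j1 <= 1.0


class TestUpdateW:
    def test_identical_classes_lambda_half(self, rng):
        mats = [rng.standard_normal((3, 15)) for _ in range(4)]
        trials = TrialSet([Trial(m, 1) for m in mats] + [Trial(m, 2) for m in mats])
        _, lam, _ = update_w(trials, h=np.array([1.0, 0.5]), b=np.ones(14))
        assert lam == pytest.approx(0.5, abs=1e-8)

    def test_beats_random_search(self, toy, rng):
        h = rng.standard_normal(4)
        b = np.r_[np.zeros(4), np.ones(17)]
        w, lam, _ = update_w(toy, h, b)
        p = ParameterSet(w, h, b)
        best = objective(toy, p, eps=0.0).j_hat
        assert lam == pytest.approx(best, rel=1e-8)
        for _ in range(200):
            wr = rng.standard_normal(3)
            jr = objective(toy, ParameterSet(wr, h, b), eps=0.0).j_hat
            assert best >= jr - 1e-10

    def test_ascent_from_arbitrary_w(self, toy, rng):
        h, b = rng.standard_normal(4), np.ones(21)
        before = objective(toy, ParameterSet(rng.standard_normal(3), h, b), eps=0.1).total
        w, _, _ = update_w(toy, h, b)
        after = objective(toy, ParameterSet(w, h, b), eps=0.1).total
        assert after >= before - 1e-12


class TestDeflation:
    def test_first_filter_empty_subspace(self):
        V = build_deflation_subspace([])
        assert V.dim == 0
        np.testing.assert_allclose(V.complement_basis(5), np.eye(5))

    def test_delta_filter_shift(self):
        e1 = np.eye(4)[0]
        V = build_deflation_subspace([e1])
        assert V.dim == 2
        np.testing.assert_array_equal(V.V[:, 0], e1)
        np.testing.assert_array_equal(V.V[:, 1], np.eye(4)[1])

    def test_two_generic_filters_rank_four(self, rng):
        h1 = rng.standard_normal(8)
        h1 /= np.linalg.norm(h1)
        h2 = rng.standard_normal(8)
        h2 -= (h2 @ h1) * h1
        h2 /= np.linalg.norm(h2)
        V = build_deflation_subspace([h1, h2])
        assert V.dim == 4
        assert np.linalg.matrix_rank(V.V) == 4

    def test_dependent_columns_pruned_with_warning(self):
        e1 = np.eye(5)[0]
        with pytest.warns(UserWarning, match="pruning"):
            V = build_deflation_subspace([e1], extra=np.column_stack([e1]))
        assert V.dim == 2


class TestUpdateH:
    def test_order_one_filter(self, toy):
        w = np.array([1.0, 0.2, -0.4])
        h, zeta = update_h(toy, w, np.ones(24), P=1)
        assert h.shape == (1,) and abs(h[0]) == pytest.approx(1.0)
        from cstfp.optimizer import _lag_covs

        Q1, Q2 = _lag_covs(toy, w, np.ones(24), 1, "count")
        q1, q2 = Q1.item(), Q2.item()
        assert zeta == pytest.approx(q1 / (q1 + q2), rel=1e-10)

    def test_result_orthogonal_to_subspace(self, toy, rng):
        h_prev = rng.standard_normal(4)
        h_prev /= np.linalg.norm(h_prev)
        V = build_deflation_subspace([h_prev])
        h, _ = update_h(toy, rng.standard_normal(3), np.ones(21), V)
        assert np.max(np.abs(V.V.T @ h)) < 1e-8
        assert np.linalg.norm(h) == pytest.approx(1.0)

    def test_beats_constrained_random_search(self, toy, rng):
        w = rng.standard_normal(3)
        b = np.ones(21)
        h_prev = rng.standard_normal(4)
        h_prev /= np.linalg.norm(h_prev)
        V = build_deflation_subspace([h_prev])
        h, _ = update_h(toy, w, b, V)
        best = objective(toy, ParameterSet(w, h, b), eps=0.0).j_hat
        U = V.complement_basis(4)
        for _ in range(500):
            hr = U @ rng.standard_normal(U.shape[1])
            jr = objective(toy, ParameterSet(w, hr, b), eps=0.0).j_hat
            assert best >= jr - 1e-10

    def test_w_h_eigenvalue_duality_at_fixed_point(self, toy):
        # alternate to convergence without deflation, then both eigenvalues
        # must equal the shared objective value
        b = np.ones(21)
        h = np.ones(4) / 2.0
        for _ in range(60):
            w, lam, _ = update_w(toy, h, b)
            h, zeta = update_h(toy, w, b, P=4)
        assert lam == pytest.approx(zeta, rel=1e-6)
        assert lam == pytest.approx(
            objective(toy, ParameterSet(w, h, b), eps=0.0).j_hat, rel=1e-8
        )


class TestUpdateB:
    def test_single_candidate_returned(self, toy, rng):
        cands = WindowCandidateSet(np.ones((1, 21)), "all_ones")
        b, _ = update_b(toy, rng.standard_normal(3), rng.standard_normal(4), cands)
        np.testing.assert_array_equal(b, np.ones(21))

    def test_huge_penalty_selects_longest_window(self, toy, rng):
        cands = contiguous_candidates(K=21, step=3, min_len=5)
        b, _ = update_b(
            toy, rng.standard_normal(3), rng.standard_normal(4), cands, eps=1e3
        )
        assert b.sum() == max(c.sum() for c in cands.candidates)

    def test_argmax_matches_objective_per_candidate(self, toy, rng):
        w, h = rng.standard_normal(3), rng.standard_normal(4)
        cands = contiguous_candidates(K=21, step=5, min_len=5)
        b, j3 = update_b(toy, w, h, cands, eps=0.2)
        totals = [
            objective(toy, ParameterSet(w, h, c), eps=0.2).total
            for c in cands.candidates
        ]
        # ParameterSet normalizes h, rescaling both class means equally, so
        # the ratio and hence the argmax are unchanged
        assert np.argmax(totals) == next(
            i for i, c in enumerate(cands.candidates) if np.array_equal(c, b)
        )
        assert j3 == pytest.approx(max(totals), rel=1e-10)


class TestFit:
    def test_objective_trace_monotone(self, rng):
        for seed in range(3):
            trials = random_trialset(
                np.random.default_rng(seed), M=4, N=40, per_class=8, scale2=1.3
            )
            model = fit(trials, small_fit_config(seed, F=2, P=6))
            for trace in model.objective_trace:
                assert np.all(np.diff(trace) >= -1e-12)

    def test_filters_mutually_orthonormal(self, rng):
        trials = random_trialset(rng, M=4, N=40, per_class=8, scale2=1.3)
        model = fit(trials, small_fit_config(0, F=3, P=8))
        H = np.column_stack([p.h for p in model.parameter_sets])
        np.testing.assert_allclose(H.T @ H, np.eye(3), atol=1e-8)

    def test_deterministic_given_seed(self, rng):
        trials = random_trialset(rng, M=3, N=30, per_class=5, scale2=1.5)
        m1 = fit(trials, small_fit_config(11, F=2, P=6))
        m2 = fit(trials, small_fit_config(11, F=2, P=6))
        assert m1.to_dict() == m2.to_dict()

    def test_serialization_roundtrip(self, rng, tmp_path):
        trials = random_trialset(rng, M=3, N=30, per_class=5, scale2=1.5)
        model = fit(trials, small_fit_config(2, F=2, P=6))
        path = tmp_path / "model.json"
        model.save(path)
        back = CstfpModel.load(path)
        assert back.to_dict() == model.to_dict()

    def test_joint_spectral_fit_dominates_plain_csp(self, rng):
        # with the window fixed to all-ones and eps = 0 the design reduces to
        # a joint spatio-spectral fit, whose criterion can only improve on a
        # spatial-only (identity-filter) solution of the same problem
        from cstfp import csp_fit

        trials = random_trialset(rng, M=3, N=60, per_class=15, scale2=1.6)
        csp_val = csp_fit(trials, c=1).eigenvalues[0]
        best = -np.inf
        for seed in range(3):
            cfg = small_fit_config(seed, F=1, P=6, eps=0.0, window_scheme="all_ones",
                                   window_params={})
            model = fit(trials, cfg)
            best = max(best, model.objective_trace[0][-1])
        assert best >= csp_val - 1e-6

    def test_recovers_late_window_and_band_of_hidden_source(self):
        # one 12.5 Hz source active only in the second half of each trial:
        # the designed filter should sit within 2 Hz of the source and the
        # window should cover the active region while trimming the silence
        from cstfp import SimConfig, SourceSpec, gaussian_bump_spectrum, generate_trials

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            N, fs, P = 80, 100.0, 21
            t = np.r_[np.zeros(40), np.ones(40)]
            src = SourceSpec(
                spectrum=gaussian_bump_spectrum(N, fs, 12.5, bandwidth_hz=0.3),
                time_window=t,
                amp_class1=np.array([1.0, 0.6, 0.1, 0.0]),
                amp_class2=np.array([0.0, 0.1, 0.6, 1.0]),
            )
            cfg = SimConfig(M=4, N=N, trials_per_class=30, fs=fs, sources=[src], seed=seed)
            trials = generate_trials(cfg)
            model = fit(
                trials,
                small_fit_config(seed, F=1, P=P, eps=0.1,
                                 window_params={"step": 5, "min_len": 10}),
            )
            p = model.parameter_sets[0]
            peak = filter_peak_frequency(p.h, fs)
            # filtered sample n draws on raw samples n .. n+P-1; map the
            # selected window back to the raw samples it uses and measure
            # how much of the true activity period (raw 40..79) it covers
            act = np.flatnonzero(p.b)
            raw_used = np.zeros(N, dtype=bool)
            for n in act:
                raw_used[n : n + P] = True
            coverage = raw_used[40:].mean()
            if abs(peak - 12.5) <= 2.0 and coverage >= 0.8:
                hits += 1
        assert hits >= 18

    def test_invalid_configs_rejected(self, rng):
        from cstfp import ValidationError

        trials = random_trialset(rng, M=3, N=30, per_class=4)
        with pytest.raises(ValidationError):
            fit(trials, small_fit_config(0, F=1, r=2))  # 2r > M
        with pytest.raises(ValidationError):
            fit(trials, small_fit_config(0, P=31))  # P > N
        with pytest.raises(ValidationError):
            fit(trials, small_fit_config(0, eps=-0.1))
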