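"""Monte Carlo search: proposals, candidate scoring, the accept loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastscode.execution import ExecutionPlan
from fastscode.io import ExpressionDataset, PseudotimeTable
from fastscode.model import (
    LatentTrajectories,
    compute_rss,
    latent_solution,
    solve_mapping,
)
from fastscode.optimizer import (
    OptimizerConfig,
    evaluate_candidates,
    initialize_b,
    optimize,
    optimize_sequential,
    optimize_with_restarts,
    propose_candidates,
)
from fastscode.synthetic import generate


class TestInitializeB:
    def test_within_range_and_deterministic(self):
        cfg = OptimizerConfig(D=4, bmin=-2.0, bmax=-1.999)
        b1 = initialize_b(cfg, np.random.default_rng(9))
        b2 = initialize_b(cfg, np.random.default_rng(9))
        assert np.all((b1 >= cfg.bmin) & (b1 <= cfg.bmax))
        assert np.array_equal(b1, b2)

    def test_coordinates_are_uniform_on_the_range(self):
        cfg = OptimizerConfig(D=4, bmin=-10.0, bmax=2.0)
        rng = np.random.default_rng(0)
        draws = np.array([initialize_b(cfg, rng) for _ in range(10_000)])
        width = cfg.bmax - cfg.bmin
        se = width / np.sqrt(12 * 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - (-4.0)) < 3 * se)


class TestProposeCandidates:
    def test_single_candidate_differs_in_one_coordinate(self):
        cfg = OptimizerConfig(D=5, candidate_batch=1)
        b = np.zeros(5)
        cand = propose_candidates(b, cfg, np.random.default_rng(1))
        assert cand.shape == (1, 5)
        assert int((cand[0] != b).sum()) == 1

    def test_scalar_dimension_always_perturbs_index_zero(self):
        cfg = OptimizerConfig(D=1, candidate_batch=16)
        b = np.array([0.123])
        cand = propose_candidates(b, cfg, np.random.default_rng(2))
        assert np.all(cand[:, 0] != b[0])

    def test_keep_incumbent_pins_row_zero(self):
        cfg = OptimizerConfig(D=3, candidate_batch=8, keep_incumbent=True)
        b = np.array([0.5, -1.0, 1.5])
        cand = propose_candidates(b, cfg, np.random.default_rng(3))
        assert np.array_equal(cand[0], b)
        assert all(int((row != b).sum()) == 1 for row in cand[1:])

    def test_perturbed_index_chosen_uniformly(self):
        cfg = OptimizerConfig(D=4, candidate_batch=1)
        rng = np.random.default_rng(4)
        b = np.zeros(4)
        n = 8000
        counts = np.zeros(4)
        for _ in range(n):
            cand = propose_candidates(b, cfg, rng)
            counts[int(np.argmax(cand[0] != b))] += 1
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(counts / n - 0.25) < 3 * se)


class TestEvaluateCandidates:
    def test_duplicate_rows_score_identically(self, small_noiseless):
        ds, t, truth = small_noiseless
        cand = np.tile(truth.b_true, (3, 1))
        rss = evaluate_candidates(ds, t, cand)
        assert rss[0] == rss[1] == rss[2]

    def test_joint_equals_one_by_one(self, small_noiseless, rng):
        """Batch scoring matches scoring each candidate alone through the
        plain sequential objective."""
        ds, t, _ = small_noiseless
        cand = rng.uniform(-8, 2, size=(6, 2))
        joint = evaluate_candidates(ds, t, cand)
        for k, b in enumerate(cand):
            Z = LatentTrajectories(latent_solution(b, t.times))
            single = compute_rss(ds, solve_mapping(ds, Z), Z)
            assert joint[k] == pytest.approx(single, rel=1e-12)

    def test_true_rates_give_zero_residual(self, small_noiseless):
        ds, t, truth = small_noiseless
        rss = evaluate_candidates(ds, t, truth.b_true[None, :])
        assert rss[0] <= 1e-10 * np.sum(ds.values**2)


class TestOptimize:
    def test_all_zero_expression_is_fit_immediately(self):
        ds = ExpressionDataset(np.zeros((4, 6)),
                               cell_ids=[f"c{i}" for i in range(6)])
        t = PseudotimeTable(list(ds.cell_ids), np.linspace(0, 1, 6))
        res = optimize(ds, t, OptimizerConfig(D=2, iterations=3, seed=5,
                                              candidate_batch=4))
        assert res.rss_best == 0.0
        assert np.all(res.mapping.W == 0.0)
        assert res.accepted == 0  # nothing can strictly improve zero

    def test_same_seed_reproduces_everything(self, small_noiseless, small_config):
        ds, t, _ = small_noiseless
        r1 = optimize(ds, t, small_config)
        r2 = optimize(ds, t, small_config)
        assert np.array_equal(r1.b_best, r2.b_best)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.score.A, r2.score.A)

    def test_batched_bs1_matches_sequential_reference(self, small_noiseless):
        ds, t, _ = small_noiseless
        for seed in range(3):
            cfg = OptimizerConfig(D=2, iterations=40, candidate_batch=1, seed=seed)
            seq = optimize_sequential(ds, t, cfg)
            bat = optimize(ds, t, cfg)
            np.testing.assert_allclose(bat.trace, seq.trace, rtol=1e-12)
            assert np.array_equal(bat.b_best, seq.b_best)

    def test_trace_non_increasing(self, small_noiseless):
        ds, t, _ = small_noiseless
        res = optimize(ds, t, OptimizerConfig(D=2, iterations=50,
                                              candidate_batch=4, seed=11))
        assert np.all(np.diff(res.trace) <= 0)
        assert res.rss_best == res.trace[-1]

    def test_plan_does_not_change_values(self, small_noiseless, small_config):
        ds, t, _ = small_noiseless
        base = optimize(ds, t, small_config)
        alt = optimize(ds, t, small_config,
                       plan=ExecutionPlan(n_workers=3, chunk_size=2,
                                          gene_batch_size=5))
        np.testing.assert_allclose(alt.trace, base.trace, rtol=1e-12)
        np.testing.assert_allclose(alt.score.A, base.score.A, rtol=1e-12,
                                   atol=1e-15)

    def test_wider_candidate_batch_does_not_hurt(self):
        """More candidates per round can only find a weakly better
        per-round minimum; compare mean final RSS over seeds."""
        finals = {1: [], 16: []}
        for seed in range(20):
            ds, t, _ = generate(G=10, C=20, D=2, noise_sd=0.3, seed=1000 + seed)
            for bs in (1, 16):
                cfg = OptimizerConfig(D=2, iterations=25, candidate_batch=bs,
                                      seed=seed)
                finals[bs].append(optimize(ds, t, cfg).rss_best)
        assert np.mean(finals[16]) <= np.mean(finals[1])

    def test_scalar_rate_reaches_grid_optimum(self):
        """D=1 search lands within grid-search tolerance of the global
        minimum of the objective over [bmin, bmax]."""
        ds, t, _ = generate(G=10, C=30, D=1, noise_sd=0.2, seed=77)
        cfg = OptimizerConfig(D=1, iterations=200, candidate_batch=64, seed=5)
        res = optimize(ds, t, cfg)
        grid = np.linspace(cfg.bmin, cfg.bmax, 2001)
        grid_rss = min(
            compute_rss(ds, solve_mapping(ds, LatentTrajectories(
                latent_solution(np.array([b]), t.times))),
                LatentTrajectories(latent_solution(np.array([b]), t.times)))
            for b in grid
        )
        assert res.rss_best <= grid_rss + 1e-6 * np.sum(ds.values**2)

    def test_restarts_return_the_best(self, small_noiseless):
        ds, t, _ = small_noiseless
        cfg = OptimizerConfig(D=2, iterations=15, candidate_batch=4, seed=21)
        multi = optimize_with_restarts(ds, t, cfg, n_restarts=4)
        single = optimize_with_restarts(ds, t, cfg, n_restarts=1)
        assert multi.rss_best <= single.rss_best + 1e-15


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    d=st.integers(1, 3),
    iters=st.integers(1, 12),
    bs=st.integers(1, 6),
    seed=st.integers(0, 1000),
    keep=st.booleans(),
)
def test_trace_monotone_for_random_configs(d, iters, bs, seed, keep):
    """The accepted-RSS trace never increases, whatever the config."""
    ds, t, _ = generate(G=6, C=12, D=d, noise_sd=0.5, seed=seed)
    cfg = OptimizerConfig(D=d, iterations=iters, candidate_batch=bs,
                          seed=seed, keep_incumbent=keep)
    res = optimize(ds, t, cfg)
    assert np.all(np.diff(res.trace) <= 0)
    assert res.rss_best == res.trace[-1]
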