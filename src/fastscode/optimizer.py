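"""Monte Carlo minimization of the RSS over the latent rate vector b.

The objective: for a candidate b, build Z[i, c] = e^{b_i t_c}, refit the
mapping W by least squares over the full gene set, and take the residual
sum of squares between X and W Z.  The search resamples one coordinate of
b at a time, uniformly on [bmin, bmax], and accepts a move only on strict
improvement, so the RSS trace is non-increasing by construction.

Two paths are provided:

* :func:`optimize_sequential` — the straight-line single-candidate
  reference loop (one coordinate resampled per iteration).
* :func:`optimize` — the batched loop: each round proposes a block of BS
  independent one-coordinate perturbations of the incumbent, scores all
  of them, and accepts the best iff it strictly improves.  At BS=1 this
  reproduces the sequential path draw-for-draw.

RNG protocol (what makes the equivalence testable): a single seeded
stream; per round, first all coordinate-index draws for the perturbed
rows, then all replacement-value draws, in row order.  The sequential
loop makes one index draw then one value draw per iteration — the same
consumption as a BS=1 round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .execution import ExecutionPlan, evaluate_partitioned
from .io import ExpressionDataset, PseudotimeTable
from .model import (
    LatentDynamics,
    LatentTrajectories,
    MappingMatrix,
    ScoreMatrix,
    compute_rss,
    latent_solution,
    reconstruct_score_matrix,
    solve_mapping,
)


@dataclass
class OptimizerConfig:
    """Search configuration.

    Defaults (D=4, 100 iterations, b in [-10, 2], BS=64) follow the
    conventions of the original reference implementation of the method;
    all are exposed on the command line and echoed into run metadata.
    """

    D: int = 4
    iterations: int = 100
    bmin: float = -10.0
    bmax: float = 2.0
    candidate_batch: int = 64
    seed: int = 0
    keep_incumbent: bool = False

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("latent dimension D must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.candidate_batch < 1:
            raise ValueError("candidate_batch (BS) must be >= 1")
        if not self.bmin < self.bmax:
            raise ValueError(f"need bmin < bmax, got [{self.bmin}, {self.bmax}]")


@dataclass
class OptimizerResult:
    """Final state of one optimization run."""

    b_best: np.ndarray
    rss_best: float
    mapping: MappingMatrix
    score: ScoreMatrix
    trace: np.ndarray
    config: OptimizerConfig
    accepted: int = 0
    per_gene_rss: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def dynamics(self) -> LatentDynamics:
        return LatentDynamics(self.b_best, self.config.bmin, self.config.bmax)


def initialize_b(config: OptimizerConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the initial b: D independent uniforms on [bmin, bmax]."""
    return rng.uniform(config.bmin, config.bmax, size=config.D)


def propose_candidates(
    b_current: np.ndarray, config: OptimizerConfig, rng: np.random.Generator
) -> np.ndarray:
    """Expand the incumbent into a BS x D block of candidate b-vectors.

    Each perturbed row equals the incumbent with exactly one coordinate
    (chosen uniformly, independently per row) replaced by a fresh uniform
    draw.  With ``keep_incumbent``, row 0 carries the incumbent unchanged
    and BS-1 perturbed rows follow.
    """
    BS = config.candidate_batch
    n_perturb = BS - 1 if config.keep_incumbent else BS
    candidates = np.tile(b_current, (BS, 1))
    if n_perturb > 0:
        idx = rng.integers(0, config.D, size=n_perturb)
        vals = rng.uniform(config.bmin, config.bmax, size=n_perturb)
        offset = 1 if config.keep_incumbent else 0
        candidates[np.arange(n_perturb) + offset, idx] = vals
    return candidates


def evaluate_candidates(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    candidates: np.ndarray,
    plan: ExecutionPlan | None = None,
) -> np.ndarray:
    """Total RSS for each candidate row, with W re-solved per candidate.

    Candidates are the outer loop and gene chunks the inner loop; each
    candidate's RSS is completed (all gene partitions aggregated) before
    the next candidate.  Values are independent of the plan partitioning.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    out = np.empty(candidates.shape[0])
    for k, b in enumerate(candidates):
        try:
            Z = LatentTrajectories(latent_solution(b, times.times))
            _, per_gene = evaluate_partitioned(dataset, Z, plan)
        except FloatingPointError as exc:
            raise FloatingPointError(f"candidate row {k}: {exc}") from exc
        out[k] = per_gene.sum()
    return out


def _finalize(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    b_best: np.ndarray,
    rss_best: float,
    trace: list[float],
    config: OptimizerConfig,
    plan: ExecutionPlan | None,
    accepted: int,
) -> OptimizerResult:
    dyn = LatentDynamics(b_best, config.bmin, config.bmax)
    Z = LatentTrajectories(latent_solution(b_best, times.times))
    mapping, per_gene = evaluate_partitioned(dataset, Z, plan)
    score = reconstruct_score_matrix(mapping, dyn)
    return OptimizerResult(
        b_best=b_best.copy(),
        rss_best=rss_best,
        mapping=mapping,
        score=score,
        trace=np.asarray(trace),
        config=config,
        accepted=accepted,
        per_gene_rss=per_gene,
    )


def optimize(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    config: OptimizerConfig,
    plan: ExecutionPlan | None = None,
    init_b: np.ndarray | None = None,
) -> OptimizerResult:
    """Batched Monte Carlo search for the minimum-RSS b.

    Runs ``config.iterations`` rounds of propose/evaluate/accept; the
    best candidate of a round replaces the incumbent only if it strictly
    lowers the RSS (ties keep the incumbent; among equal-RSS candidates
    the lowest row index wins).  Fully reproducible from (seed, config,
    inputs); the execution plan affects scheduling, never values.
    """
    rng = np.random.default_rng(config.seed)
    b = (
        np.asarray(init_b, dtype=np.float64).copy()
        if init_b is not None
        else initialize_b(config, rng)
    )
    if b.size != config.D:
        raise ValueError(f"init_b has {b.size} entries, expected D={config.D}")
    try:
        rss_best = float(
            evaluate_candidates(dataset, times, b[None, :], plan)[0]
        )
    except FloatingPointError as exc:
        raise FloatingPointError(
            f"initial RSS is not finite ({exc}); normalize pseudotime to [0, 1] "
            "or narrow [bmin, bmax]"
        ) from exc
    trace: list[float] = []
    accepted = 0
    for _ in range(config.iterations):
        candidates = propose_candidates(b, config, rng)
        rss = evaluate_candidates(dataset, times, candidates, plan)
        k = int(np.argmin(rss))  # ties -> lowest row index
        if rss[k] < rss_best:
            rss_best = float(rss[k])
            b = candidates[k].copy()
            accepted += 1
        trace.append(rss_best)
    return _finalize(dataset, times, b, rss_best, trace, config, plan, accepted)


def optimize_sequential(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    config: OptimizerConfig,
    init_b: np.ndarray | None = None,
) -> OptimizerResult:
    """Straight-line single-candidate reference loop.

    One iteration = resample one uniformly chosen coordinate of b, refit
    W on the full gene set, accept iff the RSS strictly improves.  Kept
    free of the execution machinery so it can serve as an independent
    reference for the batched path.
    """
    rng = np.random.default_rng(config.seed)
    b = (
        np.asarray(init_b, dtype=np.float64).copy()
        if init_b is not None
        else initialize_b(config, rng)
    )
    t = times.times
    X = dataset.values

    def objective(bvec: np.ndarray) -> float:
        Z = LatentTrajectories(latent_solution(bvec, t))
        W = solve_mapping(dataset, Z)
        return compute_rss(dataset, W, Z)

    rss_best = objective(b)
    trace: list[float] = []
    accepted = 0
    for _ in range(config.iterations):
        i = int(rng.integers(0, config.D))
        v = float(rng.uniform(config.bmin, config.bmax))
        cand = b.copy()
        cand[i] = v
        rss = objective(cand)
        if rss < rss_best:
            rss_best = rss
            b = cand
            accepted += 1
        trace.append(rss_best)
    dyn = LatentDynamics(b, config.bmin, config.bmax)
    Z = LatentTrajectories(latent_solution(b, t))
    mapping = solve_mapping(dataset, Z)
    score = reconstruct_score_matrix(mapping, dyn)
    return OptimizerResult(
        b_best=b.copy(),
        rss_best=rss_best,
        mapping=mapping,
        score=score,
        trace=np.asarray(trace),
        config=config,
        accepted=accepted,
        per_gene_rss=compute_rss(dataset, mapping, Z, per_gene=True),
    )


def optimize_with_restarts(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    config: OptimizerConfig,
    n_restarts: int = 1,
    plan: ExecutionPlan | None = None,
) -> OptimizerResult:
    """Independent restarts with distinct sub-seeds; the minimum-RSS
    restart wins.  Scores are never averaged across restarts."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    sub_seeds = np.random.SeedSequence(config.seed).generate_state(n_restarts)
    best: OptimizerResult | None = None
    for s in sub_seeds:
        res = optimize(dataset, times, replace(config, seed=int(s) % 2**31), plan)
        if best is None or res.rss_best < best.rss_best:
            best = res
    assert best is not None
    return best
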