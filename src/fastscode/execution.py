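"""Gene-dimension batching and the worker evaluation contract.

The per-gene regression W' = (ZZ')^{-1} Z X' factorizes over rows of X,
so genes can be partitioned into batches, each batch regressed and scored
independently (possibly on a different worker or array backend), and the
per-gene RSS contributions aggregated.  The central contract of this
module is partition invariance: the assembled W, per-gene RSS vector and
total RSS are numerically identical (to tight tolerance) under any plan.

Vocabulary: the *gene batch size* is the number of genes handed to one
worker; the *chunk size* is the number of genes evaluated in one inner
array operation within a batch.  (These batch sizes are unrelated to the
latent dynamics matrix B.)
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import ExpressionDataset
from .model import (
    LatentTrajectories,
    MappingMatrix,
    fit_mapping,
    residual_sum_of_squares,
)

#: Default working-set budget (array elements) used by the "auto" chunk rule.
DEFAULT_ELEMENT_BUDGET = 50_000_000


class AggregationError(ValueError):
    """A partition id is missing or duplicated in the partial results."""


class WorkerError(RuntimeError):
    """A worker failed; names the gene partition it was evaluating."""


@dataclass
class ExecutionPlan:
    """How the gene dimension is split across workers and inner chunks.

    ``gene_batch_size=None`` auto-balances genes across ``n_workers``
    (sizes differing by at most one).  ``chunk_size="auto"`` picks the
    largest chunk whose working set (chunk x C + chunk x D + D x C
    elements) fits ``element_budget``.
    """

    n_workers: int = 1
    gene_batch_size: int | None = None
    chunk_size: int | str = "auto"
    backend_name: str = "numpy"
    element_budget: int = DEFAULT_ELEMENT_BUDGET

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.gene_batch_size is not None and self.gene_batch_size < 1:
            raise ValueError("gene_batch_size must be >= 1")
        if isinstance(self.chunk_size, int):
            if self.chunk_size < 1:
                raise ValueError("chunk_size must be >= 1")
            if (
                self.gene_batch_size is not None
                and self.gene_batch_size < self.chunk_size
            ):
                raise ValueError("gene_batch_size must be >= chunk_size")
        elif self.chunk_size != "auto":
            raise ValueError("chunk_size must be a positive int or 'auto'")


@dataclass
class Backend:
    """An interchangeable dense-array computation provider.

    Capabilities are the four primitives the evaluation path needs; every
    registered backend must reproduce the reference backend on the probe
    suite within 1e-10 relative error.  All backends compute in double
    precision by default.
    """

    name: str
    matmul: Callable[[np.ndarray, np.ndarray], np.ndarray]
    lstsq_fit: Callable[[np.ndarray, np.ndarray], np.ndarray]
    exp: Callable[[np.ndarray], np.ndarray]
    reduce_sum: Callable[[np.ndarray], float]
    capabilities: tuple[str, ...] = (
        "dense matmul",
        "least-squares solve",
        "elementwise exp",
        "scalar reduction",
    )


_REGISTRY: dict[str, Backend] = {}

_PROBE_TOL = 1e-10


def _numpy_backend() -> Backend:
    return Backend(
        name="numpy",
        matmul=lambda a, b: a @ b,
        lstsq_fit=fit_mapping,
        exp=np.exp,
        reduce_sum=lambda a: float(np.sum(a)),
    )


def _probe_suite(backend: Backend, reference: Backend) -> None:
    """Compare a candidate backend with the reference on fixed probes."""
    rng = np.random.default_rng(20240917)
    A = rng.normal(size=(7, 5))
    B = rng.normal(size=(5, 9))
    Z = rng.normal(size=(3, 12))
    X = rng.normal(size=(6, 12))
    probes = [
        (backend.matmul(A, B), reference.matmul(A, B)),
        (backend.lstsq_fit(X, Z), reference.lstsq_fit(X, Z)),
        (backend.exp(0.1 * A), reference.exp(0.1 * A)),
        (np.asarray(backend.reduce_sum(A)), np.asarray(reference.reduce_sum(A))),
    ]
    for got, want in probes:
        err = np.linalg.norm(np.asarray(got) - want) / max(np.linalg.norm(want), 1e-300)
        if err > _PROBE_TOL:
            raise ValueError(
                f"backend {backend.name!r} failed the probe suite "
                f"(relative error {err:.3e} > {_PROBE_TOL:g})"
            )


def register_backend(backend: Backend) -> None:
    """Register a backend after it passes the probe suite."""
    if backend.name != "numpy":
        _probe_suite(backend, _REGISTRY["numpy"])
    _REGISTRY[backend.name] = backend


def get_backend(name: str) -> Backend:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_backends() -> list[str]:
    return sorted(_REGISTRY)


_REGISTRY["numpy"] = _numpy_backend()


def partition_genes(G: int, plan: ExecutionPlan) -> list[range]:
    """Split [0, G) into contiguous, disjoint, covering index ranges.

    With an explicit ``gene_batch_size`` all ranges have that size except
    possibly the last; otherwise genes are balanced across workers with
    the remainder spread over the first ranges.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if plan.gene_batch_size is not None:
        size = plan.gene_batch_size
        return [range(s, min(s + size, G)) for s in range(0, G, size)]
    n = min(plan.n_workers, G)
    base, rem = divmod(G, n)
    ranges: list[range] = []
    start = 0
    for k in range(n):
        size = base + (1 if k < rem else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


def resolve_chunk_size(plan: ExecutionPlan, C: int, D: int) -> int:
    """The "auto" chunk rule: the largest chunk whose working set
    (chunk*C + chunk*D + D*C elements) stays within the element budget."""
    if isinstance(plan.chunk_size, int):
        return plan.chunk_size
    per_gene = C + D
    budget = plan.element_budget - D * C
    return max(1, budget // per_gene)


def _evaluate_range(
    X: np.ndarray, Z: np.ndarray, idx: range, chunk: int, backend: Backend
) -> tuple[np.ndarray, np.ndarray]:
    """Fit and score genes ``idx`` in inner chunks of at most ``chunk``."""
    D = Z.shape[0]
    W_part = np.empty((len(idx), D))
    rss_part = np.empty(len(idx))
    for s in range(0, len(idx), chunk):
        rows = slice(idx.start + s, min(idx.start + s + chunk, idx.stop))
        local = slice(s, s + (rows.stop - rows.start))
        Xc = X[rows]
        Wc = backend.lstsq_fit(Xc, Z)
        W_part[local] = Wc
        rss_part[local] = residual_sum_of_squares(Xc, Wc, Z)
    return W_part, rss_part


def evaluate_partitioned(
    dataset: ExpressionDataset,
    trajectories: LatentTrajectories,
    plan: ExecutionPlan | None = None,
) -> tuple[MappingMatrix, np.ndarray]:
    """Fit W and per-gene RSS under a partitioned execution plan.

    Each gene partition is regressed independently (the regression is
    row-separable); results are assembled in gene order, so values are
    invariant to the partitioning.  A failing partition raises
    :class:`WorkerError` naming its range; partial results are never
    returned.  ``n_workers > 1`` uses a thread pool; a single-process
    plan is the default and produces identical values.
    """
    plan = plan or ExecutionPlan()
    backend = get_backend(plan.backend_name)
    X = dataset.values
    Z = trajectories.Z
    if Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"trajectories have {Z.shape[1]} columns but dataset has {X.shape[1]} cells"
        )
    G, _ = X.shape
    D = Z.shape[0]
    parts = partition_genes(G, plan)
    chunk = resolve_chunk_size(plan, X.shape[1], D)

    def run(pid_idx: tuple[int, range]) -> tuple[int, np.ndarray, np.ndarray]:
        pid, idx = pid_idx
        try:
            W_part, rss_part = _evaluate_range(X, Z, idx, chunk, backend)
        except Exception as exc:  # noqa: BLE001 - re-labelled with the range
            raise WorkerError(
                f"worker failed on gene partition [{idx.start}, {idx.stop}): {exc}"
            ) from exc
        return pid, W_part, rss_part

    tasks = list(enumerate(parts))
    if plan.n_workers > 1 and len(tasks) > 1:
        with ThreadPoolExecutor(max_workers=plan.n_workers) as pool:
            results = list(pool.map(run, tasks))
    else:
        results = [run(t) for t in tasks]

    results.sort(key=lambda r: r[0])
    W = np.vstack([r[1] for r in results])
    rss_vec = np.concatenate([r[2] for r in results])
    return MappingMatrix(W), rss_vec


def aggregate_rss(
    partials: list[tuple[int, float | np.ndarray]],
) -> tuple[float, list[np.ndarray]]:
    """Aggregate per-partition RSS contributions into one total.

    Partials are sorted by partition id and summed in that fixed order
    with compensated (exact) summation, so the total is independent of
    arrival order.  Every partition id must appear exactly once.
    """
    ids = [pid for pid, _ in partials]
    seen: set[int] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise AggregationError(f"duplicate partition ids: {dups}")
    expected = set(range(len(ids)))
    missing = sorted(expected - set(ids))
    if missing:
        raise AggregationError(f"missing partition ids: {missing}")
    ordered = sorted(partials, key=lambda p: p[0])
    values = [np.atleast_1d(np.asarray(v, dtype=np.float64)) for _, v in ordered]
    total = math.fsum(float(v.sum()) for v in values)
    return total, values
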