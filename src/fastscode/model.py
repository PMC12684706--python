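"""Closed-form core of the linear-ODE regulatory model.

The model: observed expression x(t) in R^G follows dx/dt = A x, with A
the G x G regulatory score matrix.  Direct optimization of A is avoided
by introducing latent dynamics dz = B z dt with z in R^D (D << G) and a
linear mapping x = W z.  B is diagonal with entries b_i, so the latent
trajectories have the closed form Z[i, c] = exp(b_i * t_c).  Given Z, the
mapping W is the per-gene least-squares fit of X onto Z, and the score
matrix is reconstructed as A = W diag(b) W+ where W+ is the Moore-Penrose
pseudoinverse.  Consequently rank(A) <= D.

Orientation of A: row = target gene, column = regulator, fixed by
dx/dt = A x.  Downstream edge lists depend on this convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import ExpressionDataset, PseudotimeTable

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff for least-squares solves.  Duplicate
#: entries of b make rows of Z coincide and ZZ' singular; the minimum-norm
#: solution keeps such draws from crashing a run.
LSTSQ_CUTOFF = 1e-10

_warned_rank_deficient = False


class NumericRangeError(FloatingPointError):
    """exp(b * t) overflowed; advises pseudotime normalization."""


@dataclass
class LatentDynamics:
    """Diagonal latent dynamics: the vector b (diagonal of B) and its
    uniform sampling range [bmin, bmax]."""

    b: np.ndarray
    bmin: float = -10.0
    bmax: float = 2.0

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        if self.b.size < 1:
            raise ValueError("latent dimension D must be >= 1")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("non-finite entry in b")

    @property
    def D(self) -> int:
        return self.b.size


@dataclass
class LatentTrajectories:
    """Latent solution matrix Z, D x C, entries Z[i, c] = e^{b_i t_c}."""

    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=np.float64))


@dataclass
class MappingMatrix:
    """Linear mapping W, G x D, from latent space to expression space."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite entry in W")


@dataclass
class ScoreMatrix:
    """Regulatory score matrix A, G x G; A[i, j] scores the influence of
    gene j (regulator) on gene i (target) under dx/dt = A x."""

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"score matrix must be square, got {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("non-finite entry in A")


def latent_solution(b: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Raw D x C array exp(b_i * t_c); raises on overflow."""
    b = np.atleast_1d(np.asarray(b, dtype=np.float64))
    t = np.asarray(times, dtype=np.float64)
    with np.errstate(over="ignore"):
        Z = np.exp(np.outer(b, t))
    if not np.all(np.isfinite(Z)):
        i, c = np.argwhere(~np.isfinite(Z))[0]
        raise NumericRangeError(
            f"exp(b[{i}] * t[{c}]) = exp({b[i]} * {t[c]}) is not finite; "
            "normalize pseudotime to [0, 1] or narrow [bmin, bmax]"
        )
    return Z


def build_latent_trajectories(
    dynamics: LatentDynamics, times: PseudotimeTable
) -> LatentTrajectories:
    """Construct Z from the general solution Z[i, c] = e^{b_i t_c}."""
    return LatentTrajectories(latent_solution(dynamics.b, times.times))


def fit_mapping(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Least-squares W minimizing ||X - W Z||_F, row-separable over genes.

    Solves via SVD-based minimum-norm least squares with relative cutoff
    ``LSTSQ_CUTOFF`` (never by explicit inversion of ZZ'), so coincident
    rows of Z degrade gracefully to the pseudoinverse solution.
    """
    W_T, _, rank, _ = scipy.linalg.lstsq(Z.T, X.T, cond=LSTSQ_CUTOFF)
    if rank < Z.shape[0]:
        # logged once per process: duplicate b draws recur by the thousand
        # inside the optimization loop and would otherwise flood the log
        global _warned_rank_deficient
        if not _warned_rank_deficient:
            logger.warning(
                "ZZ' is rank-deficient (rank %d < D=%d); returning the "
                "minimum-norm least-squares mapping (further occurrences "
                "logged at debug level)", rank, Z.shape[0],
            )
            _warned_rank_deficient = True
        else:
            logger.debug("rank-deficient ZZ' (rank %d < D=%d)", rank, Z.shape[0])
    return np.atleast_2d(W_T.T)


def solve_mapping(
    dataset: ExpressionDataset, trajectories: LatentTrajectories
) -> MappingMatrix:
    """Fit the G x D mapping W by per-gene least squares of X onto Z."""
    Z = trajectories.Z
    X = dataset.values
    if Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"trajectories have {Z.shape[1]} columns but dataset has {X.shape[1]} cells"
        )
    if X.shape[1] < Z.shape[0]:
        warnings.warn(
            f"fewer cells (C={X.shape[1]}) than latent dimensions (D={Z.shape[0]}); "
            "the fit is underdetermined",
            stacklevel=2,
        )
    return MappingMatrix(fit_mapping(X, Z))


def residual_sum_of_squares(
    X: np.ndarray, W: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Per-gene residual sums of squares ||X[g] - W[g] Z||^2."""
    R = X - W @ Z
    out = np.einsum("gc,gc->g", R, R)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite residual in RSS computation")
    return out


def compute_rss(
    dataset: ExpressionDataset,
    mapping: MappingMatrix,
    trajectories: LatentTrajectories,
    per_gene: bool = False,
):
    """RSS between X and W Z, summed over all genes and cells.

    The scalar is defined as the sum of the per-gene vector, so the two
    forms are consistent by construction.
    """
    vec = residual_sum_of_squares(dataset.values, mapping.W, trajectories.Z)
    if per_gene:
        return vec
    return float(vec.sum())


def reconstruct_score_matrix(
    mapping: MappingMatrix, dynamics: LatentDynamics
) -> ScoreMatrix:
    """Reconstruct A = W diag(b) W+ (W+ the Moore-Penrose pseudoinverse).

    When W has full column rank, A W = W diag(b), i.e. the columns of W
    are invariant subspaces of A with rates b.  Rank-deficient W triggers
    a warning and proceeds with pseudoinverse semantics.
    """
    W = mapping.W
    b = dynamics.b
    if W.shape[1] != b.size:
        raise ValueError(f"W has {W.shape[1]} columns but b has {b.size} entries")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        warnings.warn(
            "W is column-rank deficient; score matrix uses pseudoinverse semantics",
            stacklevel=2,
        )
    W_pinv = np.linalg.pinv(W)
    return ScoreMatrix((W * b) @ W_pinv)
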