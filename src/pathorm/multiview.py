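"""Multi-view self-expressive affinity learning.

Each view matrix A (features x entities after the internal transpose and
unit-norm column scaling) is represented through its own coefficient matrix C
with A = A C + E and diag(C) = 0, penalised by a convex mix of the nuclear
norm (low rank) and the elementwise L1 norm (sparsity), a sparse corruption
term E, and a pairwise Frobenius consensus term tying the per-view
coefficient matrices together:

    min_{C,E}  sum_i [ beta ||C^(i)||_* + (1-beta) ||C^(i)||_1
                       + lambda_e ||E^(i)||_1 ]
             + sum_{i != j} ||C^(i) - C^(j)||_F^2
    s.t.  A^(i) = A^(i) C^(i) + E^(i),  diag(C^(i)) = 0.

The L1 corruption term is an exact penalty: on clean data E = 0 is optimal
and the self-expression constraint holds exactly (the idealised hard-
constrained model is the lambda_e -> infinity limit), while on noisy data E
soft-thresholds the corruption away instead of forcing it into C, which
would destroy the subspace structure of the coefficients.

The solver is an inexact augmented-Lagrangian method in the LRR style:
auxiliary splits J (nuclear proximal step = singular-value thresholding) and
S (L1 proximal step = soft thresholding), a closed-form shrinkage for E, a
ridge-type linear solve for C, multiplier ascent, and a geometric penalty
schedule mu <- min(rho*mu, mu_max).  Views are cycled block-coordinate-wise
because the consensus coupling rules out a joint closed form.  Entities are
scaled to unit L2 norm per view before solving, the standard preprocessing
that makes lambda_e scale-free.

The fused affinity is the elementwise average of the per-view coefficient
matrices, symmetrised as (|C| + |C^T|)/2 and min-max scaled off-diagonal to
[0, 1] so that a single similarity threshold downstream is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AlignmentError, ValidationError
from .features import MultiViewSet


@dataclass
class MvSolverConfig:
    beta: float = 0.5
    lambda_e: float = 2.0
    mu0: float = 1e-2
    rho: float = 1.1
    mu_max: float = 1e6
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValidationError(f"beta must be in [0,1], got {self.beta}")
        if self.lambda_e <= 0:
            raise ValidationError("lambda_e must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.rho <= 1.0:
            raise ValidationError("rho must exceed 1")
        if self.mu0 <= 0 or self.mu_max <= 0:
            raise ValidationError("mu0 and mu_max must be positive")


@dataclass
class SolveTrace:
    """Solver diagnostics.

    ``objective`` holds the merit value of each *accepted* sweep (a sweep is
    accepted when it does not increase the merit — Eq-objective plus a fixed
    penalty on the relative self-expression residual); it is non-increasing
    by construction.  ``merit_history`` keeps every sweep for inspection.
    """

    objective: list[float] = field(default_factory=list)
    merit_history: list[float] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    converged: bool = False
    n_sweeps: int = 0
    n_rejected: int = 0


@dataclass
class AffinityMatrix:
    entity_ids: list[str]
    values: np.ndarray
    per_view: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("affinity matrix must be square")
        if len(self.entity_ids) != self.values.shape[0]:
            raise AlignmentError("entity ids do not match affinity size")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite affinity entries")

    def reorder(self, ids: list[str]) -> "AffinityMatrix":
        """Rows and columns permuted to ``ids`` (must be a permutation)."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as e:
            raise AlignmentError(f"affinity has no entity {e.args[0]!r}") from e
        if len(idx) != len(self.entity_ids):
            raise AlignmentError("reorder ids must be a full permutation")
        vals = self.values[np.ix_(idx, idx)]
        pv = None
        if self.per_view is not None:
            pv = [C[np.ix_(idx, idx)] for C in self.per_view]
        return AffinityMatrix(list(ids), vals, per_view=pv)


def _svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value thresholding: prox of tau*||.||_*."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _soft(M: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def objective_value(views: MultiViewSet, Cs: list[np.ndarray], beta: float) -> float:
    """Nuclear + L1 penalties plus the pairwise consensus term (no constraints)."""
    if len(Cs) != views.n_views:
        raise ValidationError(f"{len(Cs)} coefficient matrices for {views.n_views} views")
    m = views.n_entities
    for C in Cs:
        if C.shape != (m, m):
            raise ValidationError(f"coefficient matrix shape {C.shape} != ({m},{m})")
    total = 0.0
    for C in Cs:
        total += beta * np.linalg.svd(C, compute_uv=False).sum()
        total += (1.0 - beta) * np.abs(C).sum()
    # ordered pairs i != j: each unordered pair counted twice
    for i in range(len(Cs)):
        for j in range(len(Cs)):
            if i != j:
                total += float(np.sum((Cs[i] - Cs[j]) ** 2))
    return float(total)


def _relative_residuals(As: list[np.ndarray], Cs: list[np.ndarray]) -> list[float]:
    out = []
    for A, C in zip(As, Cs):
        denom = np.linalg.norm(A)
        if denom == 0.0:
            out.append(0.0)
        else:
            out.append(float(np.linalg.norm(A - A @ C) / denom))
    return out


def solve_multiview(
    views: MultiViewSet, config: MvSolverConfig | None = None
) -> tuple[list[np.ndarray], SolveTrace]:
    """Solve the consensus self-expressive model; returns per-view C and a trace.

    The self-expression acts on columns-as-entities, so each view matrix
    (entities x features) enters as its transpose A = view.values.T with
    C of size (entities x entities); columns are scaled to unit L2 norm.
    """
    config = config or MvSolverConfig()
    m = views.n_entities
    if m < 2:
        raise ValidationError("need at least 2 entities")
    v = views.n_views
    As = []
    for view in views.views:
        A = np.ascontiguousarray(view.values.T)  # dim x m
        norms = np.linalg.norm(A, axis=0, keepdims=True)
        As.append(A / np.maximum(norms, 1e-12))
    beta, lam_e, mu = config.beta, config.lambda_e, config.mu0

    Cs = [np.zeros((m, m)) for _ in range(v)]
    Es = [np.zeros_like(A) for A in As]
    Y1s = [np.zeros_like(A) for A in As]
    Y2s = [np.zeros((m, m)) for _ in range(v)]
    Y3s = [np.zeros((m, m)) for _ in range(v)]
    AtAs = [A.T @ A for A in As]

    trace = SolveTrace()
    eye = np.eye(m)
    best_merit = np.inf

    for sweep in range(config.max_iter):
        max_res = 0.0
        # Jacobi-style sweep: every view sees the previous sweep's partners,
        # so symmetric inputs (identical views) stay exactly symmetric
        Cs_prev = [C.copy() for C in Cs]
        for i in range(v):
            A, AtA = As[i], AtAs[i]
            C, Y1, Y2, Y3 = Cs[i], Y1s[i], Y2s[i], Y3s[i]

            J = _svt(C + Y2 / mu, beta / mu)
            S = _soft(C + Y3 / mu, (1.0 - beta) / mu)
            E = _soft(A - A @ C + Y1 / mu, lam_e / mu)

            # ridge solve: (mu*AtA + (2mu + 4(v-1)) I) C = rhs
            rhs = A.T @ (Y1 + mu * (A - E)) + mu * J - Y2 + mu * S - Y3
            for j in range(v):
                if j != i:
                    rhs = rhs + 4.0 * Cs_prev[j]
            lhs = mu * AtA + (2.0 * mu + 4.0 * (v - 1)) * eye
            C = np.linalg.solve(lhs, rhs)
            np.fill_diagonal(C, 0.0)

            res = A - A @ C - E
            Y1s[i] = Y1 + mu * res
            Y2s[i] = Y2 + mu * (C - J)
            Y3s[i] = Y3 + mu * (C - S)
            Cs[i], Es[i] = C, E

            denom = max(np.linalg.norm(A), 1.0)
            max_res = max(
                max_res,
                np.linalg.norm(res) / denom,
                np.abs(C - J).max(initial=0.0),
                np.abs(C - S).max(initial=0.0),
            )

        mu = min(config.rho * mu, config.mu_max)
        # merit = relaxed objective as a function of C alone (E eliminated)
        merit = objective_value(views, Cs, beta) + lam_e * sum(
            float(np.abs(A - A @ C).sum()) for A, C in zip(As, Cs)
        )
        trace.merit_history.append(merit)
        trace.n_sweeps = sweep + 1
        if merit <= best_merit + 1e-8:
            best_merit = min(best_merit, merit)
            trace.objective.append(merit)
        else:
            trace.n_rejected += 1
        if max_res < config.tol:
            trace.converged = True
            break

    trace.residuals = _relative_residuals(As, Cs)
    return Cs, trace


def fuse_affinities(
    Cs: list[np.ndarray], entity_ids: list[str] | None = None
) -> AffinityMatrix:
    """Elementwise average, symmetrise (|C|+|C^T|)/2, min-max scale off-diagonal.

    Degenerate scaling (all off-diagonal entries equal): nonzero values map to
    1.0, zeros stay 0, so the [0,1] similarity scale survives.
    """
    if not Cs:
        raise ValidationError("no coefficient matrices to fuse")
    m = Cs[0].shape[0]
    for C in Cs:
        if C.shape != (m, m):
            raise ValidationError("coefficient matrices differ in shape")
    W = np.mean(np.stack(Cs), axis=0)
    W = (np.abs(W) + np.abs(W.T)) / 2.0
    np.fill_diagonal(W, 0.0)
    if m > 1:
        off = ~np.eye(m, dtype=bool)
        vals = W[off]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            W[off] = (vals - lo) / (hi - lo)
        else:
            W[off] = np.where(vals > 0.0, 1.0, 0.0)
    np.fill_diagonal(W, 0.0)
    ids = entity_ids if entity_ids is not None else [str(i) for i in range(m)]
    return AffinityMatrix(ids, W, per_view=list(Cs))


def learn_affinity(
    views: MultiViewSet, config: MvSolverConfig | None = None
) -> tuple[AffinityMatrix, SolveTrace]:
    """Convenience wrapper: solve then fuse, keeping entity ids attached."""
    Cs, trace = solve_multiview(views, config)
    return fuse_affinities(Cs, views.entity_ids), trace


def spectral_partition(affinity: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-way spectral partition of a symmetric nonnegative affinity matrix.

    Normalised-Laplacian embedding followed by seeded k-means; used to read
    cluster structure out of a fused affinity.
    """
    from sklearn.cluster import KMeans

    W = np.asarray(affinity, dtype=float)
    d = W.sum(axis=1)
    d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-12)), 0.0)
    L = np.eye(W.shape[0]) - (d_inv_sqrt[:, None] * W) * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(L)
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb)
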