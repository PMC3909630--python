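"""Poisson likelihood and the MLEM update rules, with and without scatter.

The measurement model per detection bin i is Poisson with mean

    E(g_i) = SC_i + sum_k a^mu_ik f_k,

where a^mu is the attenuated system matrix and SC_i = sum_j beta_ij f_j the
first-order scatter expectation. Three multiplicative updates are provided:

* ``mlem_update`` — classic MLEM, no scatter term:
  f_j <- (f_j / s_j) * sum_i a_ij g_i / (A f)_i, with s_j = sum_i a_ij.
* ``conventional_update`` — scatter entered only as a fixed additive term in
  the denominator: f_j <- (f_j / s_j) * sum_i a_ij g_i / ((A f)_i + SC_i).
* ``proposed_update`` — derived from the full likelihood in which SC depends
  on f through beta, so the scatter gradient appears in the numerator:
  f_j <- (f_j / s_j) * sum_i [ g_i (beta_ij + a_ij) / (SC_i + (A f)_i)
  - beta_ij ].

With beta = 0 and SC = 0 the proposed update reduces exactly to
``mlem_update``. The subtraction in the proposed rule can drive pixels
negative; by default they are clamped to zero to keep the Poisson means
feasible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .geometry import ActivityImage, Sinogram
from .projector import SystemMatrix
from .scatter import ScatterKernel

__all__ = [
    "ReconConfig",
    "ReconResult",
    "log_likelihood",
    "log_likelihood_gradient",
    "mlem_update",
    "conventional_update",
    "proposed_update",
    "reconstruct",
]

METHODS = ("uncorrected", "att_cor", "conventional", "new1", "new3")


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings.

    ``initial`` is the uniform starting value f^0 (> 0). ``sc_cadence``
    controls how often (in iterations) the scatter sinogram is refreshed
    from the current estimate; 0 keeps the initial SC fixed throughout.
    """

    method: str = "att_cor"
    iterations: int = 50
    initial: float = 1.0
    epsilon: float = 1e-12
    clamp_negative: bool = True
    sc_cadence: int = 1
    record_likelihood: bool = True
    record_scatter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid: {', '.join(METHODS)}"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.initial <= 0:
            raise ValueError("initial value must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class ReconResult:
    """Final image plus per-iteration diagnostics."""

    image: np.ndarray
    grid: object
    log_likelihood: list[float] = field(default_factory=list)
    scatter_snapshots: list[np.ndarray] = field(default_factory=list)
    seconds_per_iteration: list[float] = field(default_factory=list)
    config: ReconConfig | None = None

    @property
    def activity(self) -> ActivityImage:
        return ActivityImage(np.maximum(self.image, 0.0), self.grid)


def _mat(A) -> "np.ndarray | object":
    import scipy.sparse as sp

    if isinstance(A, SystemMatrix):
        return A.matrix
    if sp.issparse(A):
        return A
    return np.asarray(A, float)


def _flat(x) -> np.ndarray:
    if isinstance(x, (Sinogram, ActivityImage)):
        return x.flat
    return np.asarray(x, float).ravel()


def _beta_ops(beta):
    """(rmatvec, column_sums) for a ScatterKernel or a dense beta array."""
    if beta is None:
        return (lambda x: 0.0), (lambda: 0.0)
    if isinstance(beta, ScatterKernel):
        return beta.rmatvec, beta.column_sums
    B = np.asarray(beta, float)
    return (lambda x: B.T @ x), (lambda: B.sum(axis=0))


def log_likelihood(f, A, g, SC=0.0) -> float:
    """Poisson log likelihood L(f) = sum_i [g_i ln(lam_i) - lam_i - ln(g_i!)].

    ``lam_i = SC_i + (A f)_i``. Bins with lam = 0 and g = 0 contribute 0;
    lam = 0 with g > 0 raises (the data are impossible under the model).
    """
    fv = _flat(f)
    gv = _flat(g)
    lam = np.asarray(SC, float).ravel() + _mat(A) @ fv if np.ndim(SC) else SC + _mat(A) @ fv
    lam = np.atleast_1d(np.asarray(lam, float))
    if np.any((lam <= 0) & (gv > 0)):
        raise ValueError("zero model mean with positive observed count")
    term = np.where(gv > 0, gv * np.log(np.where(lam > 0, lam, 1.0)), 0.0)
    return float(np.sum(term - lam - gammaln(gv + 1.0)))


def log_likelihood_gradient(f, A, g, beta=None) -> np.ndarray:
    """dL/df_j when SC = beta f is part of the model:

    grad_j = sum_i [ g_i (beta_ij + a_ij) / (SC_i + (A f)_i) - beta_ij - a_ij ].
    """
    fv = _flat(f)
    gv = _flat(g)
    M = _mat(A)
    rmat, colsum = _beta_ops(beta)
    SC = beta.estimate(fv).ravel() if isinstance(beta, ScatterKernel) else (
        np.zeros_like(gv) if beta is None else np.asarray(beta, float) @ fv
    )
    lam = SC + M @ fv
    w = np.where(lam > 0, gv / np.where(lam > 0, lam, 1.0), 0.0)
    sens = np.asarray(M.sum(axis=0)).ravel()
    return np.asarray(M.T @ w).ravel() + np.asarray(rmat(w)) - np.asarray(colsum()) - sens


def _safe_ratio(g: np.ndarray, lam: np.ndarray, eps: float) -> np.ndarray:
    return g / np.maximum(lam, eps)


def _apply_update(f, sens, backprojected, eps) -> np.ndarray:
    out = np.where(sens > 0, f * backprojected / np.maximum(sens, eps), 0.0)
    return out


def mlem_update(f, A, g, epsilon: float = 1e-12) -> np.ndarray:
    """One plain MLEM iteration (use an attenuated matrix for Att_Cor)."""
    fv = _flat(f)
    gv = _flat(g)
    M = _mat(A)
    lam = np.asarray(M @ fv).ravel()
    sens = np.asarray(M.sum(axis=0)).ravel()
    bp = np.asarray(M.T @ _safe_ratio(gv, lam, epsilon)).ravel()
    return _apply_update(fv, sens, bp, epsilon)


def conventional_update(f, A, g, SC, epsilon: float = 1e-12) -> np.ndarray:
    """One iteration of the conventional scatter-in-denominator update."""
    fv = _flat(f)
    gv = _flat(g)
    M = _mat(A)
    lam = np.asarray(M @ fv).ravel() + np.asarray(SC, float).ravel()
    sens = np.asarray(M.sum(axis=0)).ravel()
    bp = np.asarray(M.T @ _safe_ratio(gv, lam, epsilon)).ravel()
    return _apply_update(fv, sens, bp, epsilon)


def proposed_update(
    f, A, g, SC, beta, epsilon: float = 1e-12, clamp_negative: bool = True
) -> np.ndarray:
    """One iteration of the scatter-gradient update.

    ``beta`` is a ScatterKernel or dense (n x m) array; ``SC`` is normally
    the scatter sinogram beta f for the current f (callers may override).
    """
    fv = _flat(f)
    gv = _flat(g)
    M = _mat(A)
    rmat, colsum = _beta_ops(beta)
    lam = np.asarray(M @ fv).ravel() + np.asarray(SC, float).ravel()
    sens = np.asarray(M.sum(axis=0)).ravel()
    w = _safe_ratio(gv, lam, epsilon)
    bp = np.asarray(M.T @ w).ravel() + np.asarray(rmat(w)).ravel() - np.asarray(
        colsum()
    ).ravel()
    out = _apply_update(fv, sens, bp, epsilon)
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return out


def reconstruct(
    g,
    A,
    kernel: ScatterKernel | None = None,
    config: ReconConfig | None = None,
) -> ReconResult:
    """Run the configured MLEM variant from a uniform initial image.

    ``A`` should be the geometric matrix for ``uncorrected`` and the
    attenuated matrix for every corrected method. ``conventional``/``new*``
    require a scatter kernel; SC is recomputed from the running estimate
    every ``sc_cadence`` iterations.
    """
    config = config or ReconConfig()
    method = config.method
    if method in ("conventional", "new1", "new3") and kernel is None:
        raise ValueError(f"method {method!r} requires a scatter kernel")
    if isinstance(A, SystemMatrix):
        if method in ("att_cor", "conventional", "new1", "new3") and not A.attenuated:
            raise ValueError(f"method {method!r} requires an attenuated system matrix")
        grid = A.grid
        m = A.shape[1] * (grid.nz if kernel is not None and grid.nz > 1 else 1)
    else:
        grid = None
        m = np.asarray(A).shape[1]

    gv = _flat(g)
    M = _mat(A)
    import scipy.sparse as sp

    if isinstance(A, SystemMatrix) and grid is not None and gv.size > A.shape[0]:
        # multi-slice data with a per-slice matrix: stack block-diagonally
        nz = gv.size // A.shape[0]
        M = sp.block_diag([M] * nz, format="csr")
        m = A.shape[1] * nz

    fv = np.full(m, float(config.initial))
    SC = np.zeros_like(gv)
    if kernel is not None and method in ("conventional", "new1", "new3"):
        SC = kernel.estimate(fv).ravel()

    result = ReconResult(image=fv, grid=grid, config=config)
    for it in range(config.iterations):
        t0 = time.perf_counter()
        if method in ("uncorrected", "att_cor"):
            fv = mlem_update(fv, M, gv, config.epsilon)
        elif method == "conventional":
            fv = conventional_update(fv, M, gv, SC, config.epsilon)
        else:
            fv = proposed_update(
                fv, M, gv, SC, kernel, config.epsilon, config.clamp_negative
            )
        if (
            kernel is not None
            and method in ("conventional", "new1", "new3")
            and config.sc_cadence > 0
            and (it + 1) % config.sc_cadence == 0
        ):
            SC = kernel.estimate(fv).ravel()
        result.seconds_per_iteration.append(time.perf_counter() - t0)
        if config.record_likelihood:
            result.log_likelihood.append(log_likelihood(fv, M, gv, SC))
        if config.record_scatter:
            result.scatter_snapshots.append(SC.copy())
    if grid is not None:
        nz = max(1, gv.size // A.shape[0]) if isinstance(A, SystemMatrix) else 1
        result.image = fv.reshape((nz, grid.ny, grid.nx)) if nz > 1 else fv.reshape(
            grid.ny, grid.nx
        )
    else:
        result.image = fv
    return result
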