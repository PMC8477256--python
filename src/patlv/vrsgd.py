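"""Variance-reduced stochastic gradient descent (SVRG-style) reconstruction.

Minimises the TV-regularised least-squares cost

    J(X) = 1/2 || A vec(X) - vec(G) ||_2^2 + lambda TV(X)

over the image X, where A is the sparse projection operator and G the
measured velocity-potential data.  Each outer iteration takes a snapshot
x~ of the current image and computes the full misfit gradient
mu = A^T (A x~ - G); each of the Q inner iterations draws a small batch
of element blocks and forms the variance-reduced direction

    d = (Q/M) sum_{i in batch} [A_i^T (A_i x - G_i) - A_i^T (A_i x~ - G_i)] + mu,

whose expectation over batches equals the full gradient at x.  The image
is updated through the proximal operator of the (non-smooth) TV term,
x <- prox_{alpha lambda TV}(x - alpha d), with a geometrically decaying
step alpha_s = alpha0 / a^s per outer iteration s.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .das import ReconImage, das_reconstruct
from .forward import PotentialData, ProjectionOperator, Sinogram, potential_to_pressure
from .grids import Phantom

__all__ = [
    "VRSGDConfig",
    "IterationTrace",
    "ReconResult",
    "tv",
    "tv_prox",
    "cost",
    "scale_initialization",
    "vrsgd_reconstruct",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when the iteration cost blows past the divergence guard."""


@dataclasses.dataclass(frozen=True)
class VRSGDConfig:
    """Solver settings (defaults are the simulation-study values).

    ``inner_count`` defaults to the number of element blocks Q.  For
    experimental data a batch size of 10 is the recommended setting.
    """

    lambda_tv: float = 1e-5
    M: int = 5
    N: int = 30
    alpha0: float = 5.0
    decay_a: float = 1.05
    inner_count: int | None = None
    seed: int = 0
    nonneg: bool = False
    tv_inner_iters: int = 20
    tv_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lambda_tv < 0 or self.M < 1 or self.N < 1:
            raise ValueError("need lambda_tv >= 0, M >= 1, N >= 1")
        if self.alpha0 <= 0 or self.decay_a < 1:
            raise ValueError("need alpha0 > 0 and decay_a >= 1")


@dataclasses.dataclass
class IterationTrace:
    """Per-outer-iteration diagnostics."""

    cost: np.ndarray
    misfit: np.ndarray
    tv_term: np.ndarray
    rmse: np.ndarray | None
    step: np.ndarray

    def as_table(self) -> np.ndarray:
        cols = [np.arange(1, len(self.cost) + 1), self.cost, self.misfit,
                self.tv_term, self.step]
        if self.rmse is not None:
            cols.insert(4, self.rmse)
        return np.column_stack(cols)


@dataclasses.dataclass
class ReconResult:
    image: ReconImage
    trace: IterationTrace
    config: VRSGDConfig


# ---------------------------------------------------------------------------
# total variation


def _forward_diff(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with reflecting (Neumann) boundary: last row/col 0."""
    gy = np.zeros_like(x)
    gx = np.zeros_like(x)
    gy[:-1, :] = x[1:, :] - x[:-1, :]
    gx[:, :-1] = x[:, 1:] - x[:, :-1]
    return gy, gx


def _divergence(py: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Negative adjoint of ``_forward_diff`` (handles degenerate 1-pixel axes)."""
    div = np.zeros_like(py)
    if py.shape[0] > 1:
        div[0, :] += py[0, :]
        div[1:-1, :] += py[1:-1, :] - py[:-2, :]
        div[-1, :] += -py[-2, :]
    if px.shape[1] > 1:
        div[:, 0] += px[:, 0]
        div[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
        div[:, -1] += -px[:, -2]
    return div


def tv(x: np.ndarray, isotropic: bool = True) -> float:
    """Total variation of an image (isotropic by default)."""
    gy, gx = _forward_diff(np.asarray(x, float))
    if isotropic:
        return float(np.sum(np.hypot(gy, gx)))
    return float(np.sum(np.abs(gy)) + np.sum(np.abs(gx)))


def tv_prox(
    x: np.ndarray,
    tau: float,
    n_iters: int = 20,
    tol: float = 1e-4,
    isotropic: bool = True,
) -> np.ndarray:
    """Proximal operator of ``tau * TV``: solve min_u 1/2||u - x||^2 + tau TV(u).

    Chambolle's dual projection iteration; ``n_iters`` caps the dual
    sweeps and ``tol`` stops early when the dual field stalls.
    """
    if tau < 0:
        raise ValueError("prox weight tau must be >= 0")
    x = np.asarray(x, float)
    if tau == 0:
        return x.copy()
    py = np.zeros_like(x)
    px = np.zeros_like(x)
    step = 0.248  # < 1/8, the dual-step stability bound
    for _ in range(n_iters):
        u = _divergence(py, px) - x / tau
        gy, gx = _forward_diff(u)
        if isotropic:
            denom = 1.0 + step * np.hypot(gy, gx)
            py_new = (py + step * gy) / denom
            px_new = (px + step * gx) / denom
        else:
            py_new = (py + step * gy) / (1.0 + step * np.abs(gy))
            px_new = (px + step * gx) / (1.0 + step * np.abs(gx))
        delta = max(np.max(np.abs(py_new - py)), np.max(np.abs(px_new - px)))
        py, px = py_new, px_new
        if delta < tol:
            break
    return x - tau * _divergence(py, px)


# ---------------------------------------------------------------------------
# cost and initialisation


def cost(
    x: np.ndarray,
    A: ProjectionOperator,
    G: PotentialData,
    lambda_tv: float,
) -> tuple[float, float, float]:
    """Evaluate J(X) and return (J, misfit, tv_term)."""
    res = A.forward(x) - G.data
    misfit = 0.5 * float(np.sum(res * res))
    tv_term = lambda_tv * tv(np.asarray(x, float).reshape(A.grid.n, A.grid.n))
    return misfit + tv_term, misfit, tv_term


def scale_initialization(
    X0: ReconImage, A: ProjectionOperator, G: PotentialData
) -> ReconImage:
    """Rescale an initial image to the least-squares optimal amplitude.

    Returns s* X0 with s* = <A x0, G> / ||A x0||^2, the closed-form
    minimiser of ||A (s x0) - G||^2 over the scalar s.  DAS output is in
    arbitrary units, so this matters for a scale-sensitive cost.
    """
    g0 = A.forward(X0.image)
    denom = float(np.sum(g0 * g0))
    if denom == 0.0:
        import warnings

        warnings.warn("initial image maps to zero data; scale left unchanged")
        return X0
    s = float(np.sum(g0 * G.data)) / denom
    return ReconImage(s * X0.image, X0.grid, X0.method, "raw")


# ---------------------------------------------------------------------------
# the solver


def vrsgd_reconstruct(
    G: PotentialData,
    A: ProjectionOperator,
    cfg: VRSGDConfig | None = None,
    X0: ReconImage | None = None,
    truth: Phantom | None = None,
    sinogram: Sinogram | None = None,
) -> ReconResult:
    """Run the variance-reduced stochastic solver.

    If ``X0`` is absent, a DAS image is computed from ``sinogram`` (or
    from the time derivative of G when no sinogram is given), rescaled to
    the least-squares optimal amplitude, and used as the starting point.
    ``truth`` adds a per-iteration RMSE column (both images
    max-normalised) to the trace.
    """
    if cfg is None:
        cfg = VRSGDConfig()
    Q = A.Q
    if G.data.shape != (Q, A.acoustics.T):
        raise ValueError("data shape does not match the operator")
    if X0 is None:
        s = sinogram if sinogram is not None else potential_to_pressure(G)
        das = das_reconstruct(s, A.geometry, A.grid, A.acoustics, A.profile,
                              normalize=True)
        X0 = scale_initialization(das, A, G)
    x = np.asarray(X0.image, float).copy()
    if x.shape != (A.grid.n, A.grid.n):
        raise ValueError("initial image shape does not match the grid")

    inner_count = cfg.inner_count if cfg.inner_count is not None else Q
    rng = np.random.default_rng(cfg.seed)
    M = min(cfg.M, Q)

    n = A.grid.n
    Gd = G.data
    truth_img = None
    if truth is not None:
        truth_img = truth.on_grid(A.grid)
        truth_img = truth_img / np.max(np.abs(truth_img))

    j_hist = np.empty(cfg.N)
    mis_hist = np.empty(cfg.N)
    tv_hist = np.empty(cfg.N)
    rmse_hist = np.empty(cfg.N) if truth_img is not None else None
    step_hist = np.empty(cfg.N)

    j0_val, _, _ = cost(x, A, G, cfg.lambda_tv)
    guard = 10.0 * max(j0_val, np.finfo(float).tiny)

    for s_outer in range(cfg.N):
        alpha = cfg.alpha0 / (cfg.decay_a**s_outer)
        x_snap = x.copy()
        # full gradient and per-block snapshot gradients at x~
        mu = np.zeros(n * n)
        snap_grads = np.empty((Q, n * n))
        for i in range(Q):
            res_i = A.blocks[i] @ x_snap.ravel() - Gd[i]
            gi = A._blocks_T[i] @ res_i
            snap_grads[i] = gi
            mu += gi
        for _ in range(inner_count):
            batch = np.sort(rng.choice(Q, size=M, replace=False))
            d = mu.copy()
            for i in batch:
                res_i = A.blocks[i] @ x.ravel() - Gd[i]
                d += (Q / M) * (A._blocks_T[i] @ res_i - snap_grads[i])
            x = x - alpha * d.reshape(n, n)
            if cfg.lambda_tv > 0:
                x = tv_prox(x, alpha * cfg.lambda_tv,
                            n_iters=cfg.tv_inner_iters, tol=cfg.tv_tol)
            if cfg.nonneg:
                np.maximum(x, 0.0, out=x)
        j_val, mis, tvv = cost(x, A, G, cfg.lambda_tv)
        if not np.isfinite(j_val) or j_val > guard:
            raise DivergenceError(
                f"cost {j_val:.3g} exceeded 10x its initial value {j0_val:.3g} "
                f"at outer iteration {s_outer + 1}"
            )
        j_hist[s_outer] = j_val
        mis_hist[s_outer] = mis
        tv_hist[s_outer] = tvv
        step_hist[s_outer] = alpha
        if rmse_hist is not None:
            xm = np.max(np.abs(x))
            xn = x / xm if xm > 0 else x
            rmse_hist[s_outer] = float(np.sqrt(np.mean((xn - truth_img) ** 2)))

    trace = IterationTrace(j_hist, mis_hist, tv_hist, rmse_hist, step_hist)
    image = ReconImage(x, A.grid, method="VR-SGD", normalization="raw")
    return ReconResult(image=image, trace=trace, config=cfg)
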