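"""Generative Topographic Mapping: EM fit and 2-D projection.

GTM models the data as generated by a regular grid of K latent points on
[-1,1]^2, mapped into data space through an RBF basis: y_k = W' phi(x_k),
with isotropic Gaussian noise of precision beta.  EM alternates

* E-step: responsibilities r_kn proportional to exp(-beta/2 ||y_k - t_n||^2),
  normalised over the latent grid (log-sum-exp for stability);
* M-step: solve (Phi' G Phi + (lambda/beta) I) W = Phi' R T with
  G = diag(sum_n r_kn), then beta^{-1} = (1/(N D)) sum_kn r_kn ||y_k - t_n||^2.

The map is initialised from the first two principal components (the initial
manifold spans the PCA plane) and runs a fixed number of iterations — 100 by
default, no early stopping.  Defaults: 15x15 latent grid (K=225), 5x5 RBF
centres (M=25), lambda = 0.01.

The printed RBF width of 5 is stored as-is together with an interpretation
switch: ``absolute`` uses sigma = 5 in latent units (nearly constant bases
over [-1,1]^2), ``relative`` (default) uses sigma = 5 x the RBF-centre
spacing, which gives a usable map; both satisfy the model's invariants.

A compound is placed on the map at its posterior-mean latent position
sum_k r_kn x_k, which lies in the convex hull of the grid and hence in
[-1,1]^2 — the "chemical space" coordinates used for compartment-based
candidate selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist
from scipy.special import logsumexp


@dataclass
class GtmConfig:
    map_size: tuple[int, int] = (15, 15)
    rbf_grid: tuple[int, int] = (5, 5)
    rbf_sigma: float = 5.0
    sigma_mode: str = "relative"  # "relative" (x centre spacing) | "absolute"
    lambda_reg: float = 0.01
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.map_size) < 2 or min(self.rbf_grid) < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.rbf_sigma <= 0:
            raise ValueError("rbf_sigma must be > 0")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.sigma_mode not in ("relative", "absolute"):
            raise ValueError("sigma_mode must be 'relative' or 'absolute'")


@dataclass
class GtmModel:
    config: GtmConfig
    latent_points: np.ndarray  # K x 2, row-major from bottom-left
    rbf_centers: np.ndarray  # M x 2
    basis: np.ndarray  # Phi: K x (M+1), bias column last
    W: np.ndarray  # (M+1) x D
    beta: float
    #: penalized objective per iteration: data log-likelihood minus the
    #: (lambda/2)||W||^2 weight penalty.  EM increases this monotonically;
    #: the raw data log-likelihood (data_loglik_trace) can dip by ~1e-4
    #: when lambda > 0 trades likelihood for smaller weights.
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    data_loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def data_dim(self) -> int:
        return self.W.shape[1]

    @property
    def mapped_points(self) -> np.ndarray:
        """Images of the latent grid in data space: Y = Phi W (K x D)."""
        return self.basis @ self.W


def _grid(nx: int, ny: int) -> np.ndarray:
    """Regular (nx*ny) x 2 grid on [-1,1]^2, row-major from bottom-left."""
    xs = np.linspace(-1.0, 1.0, nx)
    ys = np.linspace(-1.0, 1.0, ny)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _basis_matrix(latent: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(latent, centers, "sqeuclidean")
    phi = np.exp(-d2 / (2.0 * sigma**2))
    return np.column_stack([phi, np.ones(len(latent))])


def _log_responsibilities(
    Y: np.ndarray, T: np.ndarray, beta: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log responsibilities (N x K), squared distances, and data log-likelihood."""
    d2 = cdist(T, Y, "sqeuclidean")  # N x K
    log_unnorm = -0.5 * beta * d2
    lse = logsumexp(log_unnorm, axis=1)
    log_r = log_unnorm - lse[:, None]
    N, D = T.shape
    K = Y.shape[0]
    loglik = float(
        lse.sum() + N * (0.5 * D * np.log(beta / (2 * np.pi)) - np.log(K))
    )
    return log_r, d2, loglik


def gtm_fit(X: np.ndarray, config: GtmConfig | None = None) -> GtmModel:
    """Fit a GTM to a scaled (zero-mean, unit-variance) data matrix.

    Runs exactly ``config.n_iterations`` EM iterations and records the data
    log-likelihood after each; the trace also includes the value at
    initialisation (length n_iterations + 1).
    """
    config = config or GtmConfig()
    T = np.asarray(X, dtype=float)
    if T.ndim != 2 or T.shape[1] < 2:
        raise ValueError("GTM requires a 2-D matrix with D >= 2")
    N, D = T.shape

    latent = _grid(*config.map_size)
    centers = _grid(*config.rbf_grid)
    spacing = 2.0 / (config.rbf_grid[0] - 1)
    sigma = (
        config.rbf_sigma * spacing
        if config.sigma_mode == "relative"
        else config.rbf_sigma
    )
    Phi = _basis_matrix(latent, centers, sigma)
    K, Mb = Phi.shape
    if N <= Mb:
        raise ValueError(f"need N > {Mb} samples to fit {Mb} basis weights")

    # PCA initialisation: the initial manifold spans the first two PCs
    U, S, Vt = np.linalg.svd(T - T.mean(axis=0), full_matrices=False)
    eig = (S**2) / N
    A = Vt[:2].T * np.sqrt(eig[:2])  # D x 2
    targets = latent @ A.T + T.mean(axis=0)  # K x D
    reg = config.lambda_reg if config.lambda_reg > 0 else 1e-8
    W = solve(
        Phi.T @ Phi + reg * np.eye(Mb), Phi.T @ targets, assume_a="pos"
    )
    Y = Phi @ W
    d_nn = cdist(Y, Y)
    np.fill_diagonal(d_nn, np.inf)
    half_nn = 0.5 * float(np.mean(d_nn.min(axis=1)))
    var0 = max(eig[2] if D > 2 else eig[-1], half_nn**2)
    beta = 1.0 / var0

    trace, data_trace = [], []

    def _record(loglik: float) -> None:
        data_trace.append(loglik)
        trace.append(loglik - 0.5 * config.lambda_reg * float((W**2).sum()))

    log_r, d2, loglik = _log_responsibilities(Y, T, beta)
    _record(loglik)
    for it in range(config.n_iterations):
        R = np.exp(log_r)  # N x K
        if not np.all(np.isfinite(R)):
            raise ArithmeticError(f"non-finite responsibilities at iteration {it + 1}")
        G = R.sum(axis=0)  # K
        lhs = Phi.T @ (Phi * G[:, None]) + (config.lambda_reg / beta) * np.eye(Mb)
        rhs = Phi.T @ (R.T @ T)
        try:
            W = solve(lhs, rhs, assume_a="pos")
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(
                f"singular M-step system at iteration {it + 1}"
            ) from exc
        Y = Phi @ W
        d2 = cdist(T, Y, "sqeuclidean")
        beta = 1.0 / (float((R * d2).sum()) / (N * D))
        log_r, d2, loglik = _log_responsibilities(Y, T, beta)
        _record(loglik)

    return GtmModel(
        config=config,
        latent_points=latent,
        rbf_centers=centers,
        basis=Phi,
        W=W,
        beta=beta,
        loglik_trace=np.asarray(trace),
        data_loglik_trace=np.asarray(data_trace),
    )


def responsibilities(model: GtmModel, X: np.ndarray) -> np.ndarray:
    """Posterior probabilities (N x K) that each latent point generated each row."""
    T = np.asarray(X, dtype=float)
    if T.ndim != 2 or T.shape[1] != model.data_dim:
        raise ValueError(
            f"expected {model.data_dim} columns, got {T.shape[1] if T.ndim == 2 else '?'}"
        )
    log_r, _, _ = _log_responsibilities(model.mapped_points, T, model.beta)
    return np.exp(log_r)


def gtm_project(model: GtmModel, X: np.ndarray, mode: str = "mean") -> np.ndarray:
    """2-D map coordinates for each row of X (same scaling as the fit data).

    ``mode="mean"`` (default) returns the posterior-mean latent position;
    ``mode="mode"`` returns the responsibility-argmax grid point.  Either
    way every coordinate lies in [-1, 1]^2.
    """
    R = responsibilities(model, X)
    if mode == "mean":
        return R @ model.latent_points
    if mode == "mode":
        return model.latent_points[np.argmax(R, axis=1)]
    raise ValueError("mode must be 'mean' or 'mode'")


def plot_map(
    coords: np.ndarray,
    labels: np.ndarray | None = None,
    ax=None,
    grid_divisions: int = 8,
):
    """Scatter of map coordinates with the compartment grid overlaid."""
    import matplotlib.pyplot as plt  # optional dependency, imported lazily

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    c = None if labels is None else np.asarray(labels).astype(int)
    ax.scatter(coords[:, 0], coords[:, 1], s=6, c=c, cmap="coolwarm", alpha=0.6)
    for edge in np.linspace(-1, 1, grid_divisions + 1):
        ax.axhline(edge, color="grey", lw=0.4)
        ax.axvline(edge, color="grey", lw=0.4)
    ax.set_xlim(-1.02, 1.02)
    ax.set_ylim(-1.02, 1.02)
    ax.set_xlabel("latent x")
    ax.set_ylabel("latent y")
    return ax
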