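"""Sparse partial-correlation (Gaussian graphical model) estimation.

A person's contemporaneous symptom network is the partial-correlation
structure implied by a sparse precision matrix, estimated by the
graphical lasso: maximize ``log det T - tr(S T) - lam * sum_{i!=j}|t_ij|``
over positive-definite T, with the diagonal unpenalized.  The penalty is
chosen along a log-spaced path by the extended Bayesian information
criterion (EBIC), whose hyperparameter gamma trades off discovery against
sparsity.  Edge weights are the partial correlations
``w_ij = -t_ij / sqrt(t_ii t_jj)``.

Two configurations mirror the two analysis approaches: temporal basis
columns embedded alongside symptoms as nodes (nonstationarity partialed
out, and symptom-temporal edges showing which symptoms trend or cycle),
or detrended residual symptoms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso

from .detrend import DetrendResult
from .ema_data import EmaDataset
from .temporal_basis import TemporalBasis

__all__ = [
    "NetworkConfig",
    "GlassoSolution",
    "NetworkEstimate",
    "correlation_matrix",
    "glasso_solve",
    "ebic",
    "estimate_network",
    "approach1_embedded_network",
    "approach2_residual_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation: str = "pearson"  # or "spearman"
    max_iter: int = 200
    tol: float = 1e-4  # CD dual-gap; looser than default, ordinal data rarely does better


@dataclass
class GlassoSolution:
    """Penalized precision estimate at a single penalty value."""

    precision: np.ndarray
    lam: float
    objective: float
    converged: bool
    n_iter: int


@dataclass
class NetworkEstimate:
    """A fitted partial-correlation network with selection metadata."""

    nodes: tuple[str, ...]
    kinds: tuple[str, ...]  # "symptom" | "temporal" per node
    W: np.ndarray  # partial correlations, symmetric, zero diagonal
    precision: np.ndarray
    S: np.ndarray
    lambda_path: np.ndarray
    selected_lambda: float
    ebic_gamma: float
    n_obs: int
    uninterpretable: bool = False
    notes: tuple[str, ...] = field(default=())

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.W, k=1)
        return int((self.W[iu] != 0).sum())

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                if self.W[i, j] != 0:
                    out.append((self.nodes[i], self.nodes[j], float(self.W[i, j])))
        return out

    def edge_frame(self) -> pd.DataFrame:
        kinds = dict(zip(self.nodes, self.kinds))
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "weight": w,
                "kind_a": kinds[a],
                "kind_b": kinds[b],
            }
            for a, b, w in self.edges()
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "kind_a", "kind_b"])

    def subnetwork(self, kind: str) -> np.ndarray:
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        return self.W[np.ix_(idx, idx)]


def correlation_matrix(Y: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Sample correlation matrix of the complete-case node matrix."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    sds = Y.std(axis=0, ddof=0)
    if (sds < 1e-12).any():
        j = int(np.argmin(sds))
        raise ValueError(f"constant column at index {j}")
    if n < p:
        warnings.warn(f"n={n} < p={p}: correlation matrix is singular", stacklevel=2)
    if method == "pearson":
        S = np.corrcoef(Y, rowvar=False)
    elif method == "spearman":
        S = stats.spearmanr(Y).statistic
        S = np.atleast_2d(S)
        if S.shape != (p, p):  # p == 2 returns a scalar
            r = float(S.ravel()[0])
            S = np.array([[1.0, r], [r, 1.0]])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def _nearest_psd(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, eps, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _objective(S: np.ndarray, T: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(T)
    if sign <= 0:
        return -np.inf
    off = np.abs(T).sum() - np.abs(np.diag(T)).sum()
    return float(logdet - np.trace(S @ T) - lam * off)


def glasso_solve(S: np.ndarray, lam: float, config: NetworkConfig = NetworkConfig()) -> GlassoSolution:
    """Solve the graphical lasso at one penalty value.

    At ``lam=0`` the maximizer is the unpenalized MLE ``S^-1`` and is
    computed in closed form.  An input matrix that is not positive
    semidefinite is repaired to the nearest correlation matrix with a
    warning.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.linalg.eigvalsh(S).min() < -1e-10:
        warnings.warn("S not positive semidefinite; applying nearest-PSD repair", stacklevel=2)
        S = _nearest_psd(S)
    if lam == 0.0:
        T = np.linalg.inv(S)
        T = (T + T.T) / 2.0
        return GlassoSolution(T, 0.0, _objective(S, T, 0.0), True, 0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence tracked via n_iter
            _, T, n_iter = graphical_lasso(
                S, alpha=lam, max_iter=config.max_iter, tol=config.tol,
                return_n_iter=True,
            )
    except FloatingPointError as exc:
        raise RuntimeError(f"graphical lasso failed at lam={lam:.4g}: {exc}") from exc
    T = (T + T.T) / 2.0
    converged = n_iter < config.max_iter
    return GlassoSolution(T, float(lam), _objective(S, T, lam), converged, int(n_iter))


def ebic(sol: GlassoSolution, S: np.ndarray, n_obs: int, gamma: float) -> float:
    """Extended BIC of a glasso solution.

    ``-2 l(T) + E log n + 4 gamma E log p`` where
    ``l = (n/2)(log det T - tr(S T))`` and E counts nonzero off-diagonal
    upper-triangle entries.  ``gamma=0`` reduces to the ordinary BIC.
    """
    T = sol.precision
    p = T.shape[0]
    sign, logdet = np.linalg.slogdet(T)
    ll = (n_obs / 2.0) * (logdet - np.trace(S @ T))
    iu = np.triu_indices(p, k=1)
    E = int((np.abs(T[iu]) > 1e-10).sum())
    return float(-2.0 * ll + E * np.log(n_obs) + 4.0 * gamma * E * np.log(p))


def precision_to_partial(T: np.ndarray) -> np.ndarray:
    """Partial correlations ``w_ij = -t_ij / sqrt(t_ii t_jj)``, zero diagonal."""
    d = np.sqrt(np.diag(T))
    W = -T / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    W[np.abs(W) < 1e-10] = 0.0
    return W


def estimate_network(
    Y: np.ndarray,
    nodes,
    kinds=None,
    config: NetworkConfig = NetworkConfig(),
) -> NetworkEstimate:
    """Estimate a sparse partial-correlation network with EBIC selection.

    Evaluates a log-spaced penalty path from ``lam_max`` (the largest
    off-diagonal |correlation|, above which the graph is empty) down to
    ``lambda_min_ratio * lam_max`` and keeps the minimum-EBIC solution.
    """
    Y = np.asarray(Y, dtype=float)
    nodes = tuple(nodes)
    kinds = tuple(kinds) if kinds is not None else ("symptom",) * len(nodes)
    n, p = Y.shape
    if p < 2:
        W = np.zeros((p, p))
        return NetworkEstimate(
            nodes=nodes, kinds=kinds, W=W, precision=np.ones((p, p)),
            S=np.ones((p, p)), lambda_path=np.array([]), selected_lambda=np.nan,
            ebic_gamma=config.ebic_gamma, n_obs=n, uninterpretable=True,
            notes=("fewer than 2 nodes: degenerate network",),
        )
    S = correlation_matrix(Y, method=config.correlation)
    lam_max = float(np.max(np.abs(S - np.eye(p))))
    if lam_max < 1e-12:
        lam_max = 1e-6  # all-zero correlations: any penalty gives the empty graph
    path = np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)
    best = None
    best_score = np.inf
    for lam in path:
        try:
            sol = glasso_solve(S, float(lam), config)
        except RuntimeError:
            continue
        score = ebic(sol, S, n, config.ebic_gamma)
        if score < best_score:
            best_score, best = score, sol
    if best is None:
        raise RuntimeError("graphical lasso failed along the entire path")
    notes: list[str] = []
    if not best.converged:
        notes.append(
            f"selected solution stopped at max_iter={config.max_iter} "
            f"(lam={best.lam:.4g})"
        )
    W = precision_to_partial(best.precision)
    return NetworkEstimate(
        nodes=nodes,
        kinds=kinds,
        W=W,
        precision=best.precision,
        S=S,
        lambda_path=path,
        selected_lambda=best.lam,
        ebic_gamma=config.ebic_gamma,
        n_obs=n,
        uninterpretable=p < 3,
        notes=tuple(
            notes + (["fewer than 3 nodes: centrality cannot be interpreted"] if p < 3 else [])
        ),
    )


def approach1_embedded_network(
    ds: EmaDataset,
    basis: TemporalBasis,
    config: NetworkConfig = NetworkConfig(),
) -> NetworkEstimate:
    """Network over endorsed symptoms plus the standardized temporal columns.

    Temporal nodes partial nonstationarity out of the symptom-symptom
    edges; a symptom-temporal edge marks a trend or cycle in that symptom.
    ``ds`` must be complete-case on the endorsed symptoms and ``basis``
    standardized on the same rows.
    """
    if not basis.standardized:
        raise ValueError("basis must be standardized")
    if basis.X.shape[0] != ds.n_obs:
        raise ValueError("basis rows must align with dataset rows")
    Y = np.column_stack([ds.Y, basis.X])
    nodes = ds.symptoms + basis.columns
    kinds = ("symptom",) * len(ds.symptoms) + ("temporal",) * len(basis.columns)
    return estimate_network(Y, nodes, kinds, config)


def approach2_residual_network(
    detrended: list[DetrendResult],
    config: NetworkConfig = NetworkConfig(),
) -> NetworkEstimate:
    """Network over detrended residual symptom series only.

    With fewer than 2 endorsed symptoms a degenerate network is returned,
    flagged uninterpretable rather than raising: a person can validly
    endorse a single symptom.
    """
    nodes = tuple(r.symptom for r in detrended)
    if len(detrended) < 2:
        p = len(detrended)
        return NetworkEstimate(
            nodes=nodes, kinds=("symptom",) * p, W=np.zeros((p, p)),
            precision=np.eye(max(p, 1))[:p, :p], S=np.eye(max(p, 1))[:p, :p],
            lambda_path=np.array([]), selected_lambda=np.nan,
            ebic_gamma=config.ebic_gamma,
            n_obs=detrended[0].n_obs if detrended else 0,
            uninterpretable=True,
            notes=("fewer than 2 endorsed symptoms: degenerate network",),
        )
    n = {r.residuals.size for r in detrended}
    if len(n) != 1:
        raise ValueError("residual series must share identical rows")
    Y = np.column_stack([r.residuals for r in detrended])
    return estimate_network(Y, nodes, ("symptom",) * len(nodes), config)
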