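"""Conditional mutual information estimators.

Two estimators of I(X; Y | Z) in nats:

* :func:`gaussian_cmi` — covariance-based plug-in estimator, exact for
  jointly Gaussian variables and equivalent to (half) the Granger
  log-likelihood ratio.  Under conditional independence, 2*M*I_hat is
  asymptotically chi-squared with dim(x)*dim(y) degrees of freedom, which
  gives an analytic null distribution (:func:`gaussian_null_cdf`).
* :func:`ksg_cmi` — Kraskov-Stoegbauer-Grassberger nearest-neighbor
  estimator (algorithm 1) and its Frenzel-Pompe extension to the
  conditional case.  Model-free; detects nonlinear dependencies.

Raw estimates are returned unclipped: at finite sample size both
estimators can return negative values when the true CMI is near zero, and
the statistical tests (not the estimate sign) decide significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import chi2

__all__ = [
    "CmiEstimate",
    "gaussian_cmi",
    "gaussian_cmi_from_cov",
    "gaussian_null_cdf",
    "gaussian_null_quantile",
    "ksg_cmi",
]


@dataclass(frozen=True)
class CmiEstimate:
    """A CMI estimate in nats, with the context needed to test it."""

    value: float
    estimator_id: str
    m: int
    k: int | None = None


def _as_matrix(a: np.ndarray | None, name: str, m: int | None) -> np.ndarray:
    if a is None:
        a = np.empty((0 if m is None else m, 0))
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, np.newaxis]
    if a.ndim != 2:
        raise ValueError(f"{name} must be a vector or 2-D matrix")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite values in {name}")
    if m is not None and a.shape[0] != m:
        raise ValueError(
            f"{name} has {a.shape[0]} samples, expected {m}"
        )
    return a


def _logdet(cov: np.ndarray, idx: np.ndarray) -> float:
    """log-determinant of a covariance submatrix; 0 for the empty set."""
    if len(idx) == 0:
        return 0.0
    sub = cov[np.ix_(idx, idx)]
    sign, ld = np.linalg.slogdet(sub)
    if sign <= 0 or not np.isfinite(ld):
        raise np.linalg.LinAlgError(
            f"singular covariance over columns {list(idx)}: "
            "collinear or constant variables"
        )
    return ld


def gaussian_cmi_from_cov(
    cov: np.ndarray,
    idx_x,
    idx_y,
    idx_z=(),
) -> float:
    """Gaussian CMI from a precomputed joint covariance matrix.

    ``I(x; y | z) = 1/2 [ln det S_xz + ln det S_yz - ln det S_xyz - ln det S_z]``
    where the subscripts select rows/columns of ``cov``.  With exact
    covariances this is the population CMI; with sample covariances it is
    the plug-in estimate.
    """
    ix = np.asarray(idx_x, dtype=int)
    iy = np.asarray(idx_y, dtype=int)
    iz = np.asarray(idx_z, dtype=int)
    ld_xz = _logdet(cov, np.concatenate([ix, iz]))
    ld_yz = _logdet(cov, np.concatenate([iy, iz]))
    ld_xyz = _logdet(cov, np.concatenate([ix, iy, iz]))
    ld_z = _logdet(cov, iz)
    return 0.5 * (ld_xz + ld_yz - ld_xyz - ld_z)


def gaussian_cmi(x, y, z=None) -> CmiEstimate:
    """Covariance-based estimate of I(x; y | z) in nats.

    Covariances use mean removal and 1/M normalization; the normalization
    constant cancels in the log-determinant differences.  With ``z`` empty
    this reduces to Gaussian mutual information, -1/2 ln(1 - rho^2) in the
    bivariate case.

    Raises on singular (collinear) covariance and on non-finite input.
    """
    x = _as_matrix(x, "x", None)
    m = x.shape[0]
    y = _as_matrix(y, "y", m)
    z = _as_matrix(z, "z", m)
    n_var = x.shape[1] + y.shape[1] + z.shape[1]
    if m < n_var + 2:
        raise ValueError(
            f"need at least {n_var + 2} samples for {n_var} variables, got {m}"
        )
    joint = np.hstack([x, y, z])
    centred = joint - joint.mean(axis=0)
    cov = centred.T @ centred / m
    ix = np.arange(x.shape[1])
    iy = np.arange(x.shape[1], x.shape[1] + y.shape[1])
    iz = np.arange(x.shape[1] + y.shape[1], n_var)
    value = gaussian_cmi_from_cov(cov, ix, iy, iz)
    return CmiEstimate(value=value, estimator_id="gaussian", m=m)


def gaussian_null_cdf(value: float, m: int, dim_x: int = 1, dim_y: int = 1) -> float:
    """P(I_hat <= value) under conditional independence (Gaussian estimator).

    Uses the likelihood-ratio asymptotics 2*M*I_hat ~ chi2 with
    dim_x*dim_y degrees of freedom.  Monotone nondecreasing in ``value``.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if value <= 0:
        return 0.0
    return float(chi2.cdf(2.0 * m * value, df=dim_x * dim_y))


def gaussian_null_quantile(p: float, m: int, dim_x: int = 1, dim_y: int = 1) -> float:
    """Inverse of :func:`gaussian_null_cdf` in its continuous range."""
    if m <= 0:
        raise ValueError("m must be positive")
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    return float(chi2.ppf(p, df=dim_x * dim_y) / (2.0 * m))


def _strict_count(tree: cKDTree, points: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Neighbors strictly inside radius eps, excluding the point itself."""
    # shrink the radius to the previous float so boundary points are excluded
    counts = tree.query_ball_point(
        points, np.nextafter(eps, 0.0), p=np.inf, return_length=True
    )
    return np.asarray(counts) - 1


def ksg_cmi(
    x,
    y,
    z=None,
    k: int = 4,
    tie_noise: float = 1e-8,
    seed: int = 0,
) -> CmiEstimate:
    """Nearest-neighbor estimate of I(x; y | z) in nats.

    Kraskov algorithm 1 with the max-norm in every subspace: for each
    point, the distance ``eps_i`` to its k-th nearest neighbor in the
    joint space sets a radius, and neighbors strictly inside that radius
    are counted in the marginal subspaces.  With ``z`` empty,

        ``I = psi(k) + psi(M) - <psi(n_x + 1) + psi(n_y + 1)>``,

    and in the conditional (Frenzel-Pompe) form,

        ``I = psi(k) - <psi(n_xz + 1) + psi(n_yz + 1) - psi(n_z + 1)>``.

    ``tie_noise`` adds deterministic seeded Gaussian jitter at amplitude
    ``tie_noise * sd(column)`` to break ties (repeated values are common
    after, e.g., modulo maps); the estimate is deterministic given the
    seed.  A constant column is rejected: its distances are degenerate and
    jitter proportional to a zero standard deviation cannot break them.
    """
    x = _as_matrix(x, "x", None)
    m = x.shape[0]
    y = _as_matrix(y, "y", m)
    z = _as_matrix(z, "z", m)
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= k:
        raise ValueError(f"need more than k={k} samples, got {m}")
    joint = np.hstack([x, y, z])
    sd = joint.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"constant column {bad}: degenerate distances")
    if tie_noise > 0:
        rng = np.random.default_rng(seed)
        joint = joint + tie_noise * sd * rng.standard_normal(joint.shape)

    dx, dy = x.shape[1], y.shape[1]
    xj = joint[:, :dx]
    yj = joint[:, dx : dx + dy]
    zj = joint[:, dx + dy :]

    eps = cKDTree(joint).query(joint, k=k + 1, p=np.inf)[0][:, -1]

    if zj.shape[1] == 0:
        n_x = _strict_count(cKDTree(xj), xj, eps)
        n_y = _strict_count(cKDTree(yj), yj, eps)
        value = (
            digamma(k)
            + digamma(m)
            - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
        )
    else:
        xz = np.hstack([xj, zj])
        yz = np.hstack([yj, zj])
        n_xz = _strict_count(cKDTree(xz), xz, eps)
        n_yz = _strict_count(cKDTree(yz), yz, eps)
        n_z = _strict_count(cKDTree(zj), zj, eps)
        value = digamma(k) - np.mean(
            digamma(n_xz + 1) + digamma(n_yz + 1) - digamma(n_z + 1)
        )
    return CmiEstimate(value=float(value), estimator_id="ksg", m=m, k=k)
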