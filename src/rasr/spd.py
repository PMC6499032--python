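"""Geometry of symmetric positive-definite (SPD) covariance matrices.

EEG covariance matrices live on the SPD manifold, a negatively curved
Riemannian space.  Under the affine-invariant metric

    d(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F

straight lines become geodesics, the arithmetic mean becomes the Karcher
mean (Riemannian centre of mass), and PCA becomes principal geodesic
analysis (PGA).  This module implements exactly the primitives the
Riemannian variant of artifact subspace reconstruction needs:

* matrix square roots (the "mixing matrix" M with M M^T = U),
* geodesic distance, exp/log maps,
* weighted Karcher means,
* the Euclidean (L1) geometric median used by classic ASR calibration,
* tangent-space PGA,
* the unbiased per-segment covariance estimator X X^T / (t - 1).

All functions accept and return plain ``numpy`` arrays.  Inputs are
validated against the SPD invariants (symmetry to 1e-10 relative, strictly
positive spectrum); rank-deficient estimates can be nudged onto the
manifold with :func:`regularize_spd`.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "InvalidCovarianceError",
    "ConvergenceError",
    "is_spd",
    "regularize_spd",
    "sym_sqrt",
    "sym_inv_sqrt",
    "sym_logm",
    "sym_expm",
    "geodesic_distance",
    "geodesic_distance_inf",
    "log_map",
    "exp_map",
    "karcher_mean",
    "geodesic_interpolate",
    "geometric_median_euclidean",
    "pga",
    "sym_to_vec",
    "vec_to_sym",
    "sample_covariance_unbiased",
]

SYM_TOL = 1e-10


class InvalidCovarianceError(ValueError):
    """Raised when a matrix violates the SPD invariants."""


class ConvergenceError(RuntimeError):
    """Raised when a fixed-point iteration fails to reach its tolerance."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(f"{message} (final gradient norm {gradient_norm:.3e})")
        self.gradient_norm = gradient_norm


def _check_square(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != U.shape[1]:
        raise InvalidCovarianceError(f"expected a square matrix, got {U.shape}")
    return U


def _check_spd(U: np.ndarray, what: str = "matrix") -> np.ndarray:
    U = _check_square(U)
    nrm = np.linalg.norm(U)
    if nrm == 0 or np.linalg.norm(U - U.T) > SYM_TOL * max(nrm, 1.0):
        raise InvalidCovarianceError(f"{what} is not symmetric within tolerance")
    return U


def is_spd(U: np.ndarray, tol: float = SYM_TOL) -> bool:
    """True if ``U`` is symmetric (to ``tol`` relative) with positive spectrum."""
    U = np.asarray(U, float)
    if U.ndim != 2 or U.shape[0] != U.shape[1]:
        return False
    nrm = np.linalg.norm(U)
    if nrm == 0 or np.linalg.norm(U - U.T) > tol * max(nrm, 1.0):
        return False
    return bool(np.linalg.eigvalsh((U + U.T) / 2).min() > 0)


def regularize_spd(U: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Symmetrise and add ``eps * trace(U)/c`` to the diagonal if needed.

    Rank-deficient sample covariances (short or degenerate segments) are
    pushed strictly inside the SPD cone so that logarithms and inverse
    square roots exist.  An all-zero matrix gets ``eps * I``.
    """
    U = _check_square(U)
    U = (U + U.T) / 2.0
    c = U.shape[0]
    scale = np.trace(U) / c
    if scale <= 0:
        scale = 1.0
    lam_min = np.linalg.eigvalsh(U).min()
    if lam_min <= eps * scale:
        U = U + (eps * scale - min(lam_min, 0.0)) * np.eye(c)
    return U


def _eigh_spd(U: np.ndarray, what: str = "matrix") -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition (ascending) with a strict positivity check."""
    U = _check_spd(U, what)
    w, Q = np.linalg.eigh((U + U.T) / 2.0)
    if w.min() <= 0:
        raise InvalidCovarianceError(
            f"{what} is not positive definite (min eigenvalue {w.min():.3e})")
    return w, Q


def sym_sqrt(U: np.ndarray) -> np.ndarray:
    """Symmetric square root: the mixing matrix M with ``M @ M.T == U``."""
    w, Q = _eigh_spd(U, "covariance")
    return (Q * np.sqrt(w)) @ Q.T


def sym_inv_sqrt(U: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root U^{-1/2}."""
    w, Q = _eigh_spd(U, "covariance")
    return (Q / np.sqrt(w)) @ Q.T


def sym_logm(U: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    w, Q = _eigh_spd(U, "matrix")
    return (Q * np.log(w)) @ Q.T


def sym_expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = _check_square(S)
    S = (S + S.T) / 2.0
    w, Q = np.linalg.eigh(S)
    return (Q * np.exp(w)) @ Q.T


def geodesic_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    ``d(A, B) = ||logm(A^{-1/2} B A^{-1/2})||_F``; symmetric in its
    arguments, zero iff ``A == B`` and invariant under congruence
    ``A -> W A W^T``.
    """
    A = _check_square(A)
    B = _check_square(B)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    # eigvals of A^{-1} B == eigvals of A^{-1/2} B A^{-1/2}; solve the
    # generalized problem directly for numerical symmetry in A, B.
    w = scipy.linalg.eigvalsh(B, A)
    if w.min() <= 0:
        raise InvalidCovarianceError("inputs are not both positive definite")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def geodesic_distance_inf(A: np.ndarray, B: np.ndarray) -> float:
    """L-infinity geodesic distance: ``max_i |log lambda_i(A^{-1} B)|``.

    The largest log generalized eigenvalue.  Unlike the Frobenius-type
    distance, which pools jitter from every dimension, this statistic
    responds to a variance burst confined to a single direction — the
    signature of a stereotypical artifact.
    """
    A = _check_square(A)
    B = _check_square(B)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    w = scipy.linalg.eigvalsh(B, A)
    if w.min() <= 0:
        raise InvalidCovarianceError("inputs are not both positive definite")
    return float(np.abs(np.log(w)).max())


def log_map(base: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Riemannian log map at ``base``: the tangent vector pointing to ``P``.

    ``Log_B(P) = B^{1/2} logm(B^{-1/2} P B^{-1/2}) B^{1/2}`` (symmetric).
    """
    Bs = sym_sqrt(base)
    Bis = sym_inv_sqrt(base)
    inner = sym_logm(regularize_spd(Bis @ _check_square(P) @ Bis))
    V = Bs @ inner @ Bs
    return (V + V.T) / 2.0


def exp_map(base: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Riemannian exp map at ``base``; inverse of :func:`log_map`."""
    Bs = sym_sqrt(base)
    Bis = sym_inv_sqrt(base)
    V = _check_square(V)
    inner = sym_expm(Bis @ ((V + V.T) / 2.0) @ Bis)
    P = Bs @ inner @ Bs
    return (P + P.T) / 2.0


def geodesic_interpolate(A: np.ndarray, B: np.ndarray, w: float) -> np.ndarray:
    """Point at parameter ``w`` on the geodesic from ``A`` (w=0) to ``B`` (w=1).

    Closed form ``A^{1/2} (A^{-1/2} B A^{-1/2})^w A^{1/2}``; ``w=0.5`` is the
    geometric (midpoint) mean of the pair.
    """
    As = sym_sqrt(A)
    Ais = sym_inv_sqrt(A)
    lam, Q = _eigh_spd(regularize_spd(Ais @ _check_square(B) @ Ais), "inner matrix")
    inner = (Q * lam ** w) @ Q.T
    P = As @ inner @ As
    return (P + P.T) / 2.0


def karcher_mean(
    mats,
    weights=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Weighted Karcher mean (Riemannian centre of mass) of SPD matrices.

    Minimises ``sum_i w_i d(C_i, U)^2`` by the standard fixed-point
    iteration ``U <- Exp_U(sum_i w_i Log_U(C_i))``, initialised at the
    weighted Euclidean mean.  Convergence is declared when the tangent
    gradient has Frobenius norm below ``tol`` (relative to the mean trace
    scale).

    Parameters
    ----------
    mats : sequence of ndarray
        SPD matrices, all the same dimension.
    weights : sequence of float, optional
        Nonnegative, summing to one.  Defaults to uniform.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` iterations do not reach ``tol``.
    """
    mats = [regularize_spd(_check_spd(np.asarray(m, float))) for m in mats]
    if len(mats) == 0:
        raise ValueError("need at least one matrix")
    c = mats[0].shape[0]
    for m in mats:
        if m.shape != (c, c):
            raise ValueError("matrices differ in dimension")
    if weights is None:
        weights = np.full(len(mats), 1.0 / len(mats))
    weights = np.asarray(weights, float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    if len(mats) == 1:
        return mats[0]
    # drop zero-weight entries; a single survivor is its own mean
    keep = weights > 0
    if keep.sum() == 1:
        return mats[int(np.flatnonzero(keep)[0])]

    # two-matrix case has the closed-form geodesic solution
    if keep.sum() == 2:
        i, j = np.flatnonzero(keep)
        return geodesic_interpolate(mats[i], mats[j],
                                    weights[j] / (weights[i] + weights[j]))

    U = np.einsum("i,ijk->jk", weights, np.array(mats))
    U = regularize_spd(U)
    scale = max(np.trace(U) / c, np.finfo(float).tiny)
    grad_norm = np.inf
    for _ in range(max_iter):
        Us = sym_sqrt(U)
        Uis = sym_inv_sqrt(U)
        grad = np.zeros_like(U)
        for w_i, C in zip(weights, mats):
            if w_i == 0:
                continue
            grad += w_i * sym_logm(regularize_spd(Uis @ C @ Uis))
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol * scale:
            return U
        U = Us @ sym_expm(grad) @ Us
        U = (U + U.T) / 2.0
    raise ConvergenceError("Karcher mean did not converge", grad_norm)


def geometric_median_euclidean(
    mats,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Euclidean L1 (geometric) median of a set of covariance matrices.

    The robust centre classic ASR calibration uses:
    ``argmin_U sum_i ||C_i - U||_F``, computed with the Weiszfeld
    iteration.  When an iterate lands on a data point the standard
    tie rule applies: the pull of the remaining points must exceed the
    unit "weight" of the coincident point for the iterate to move.
    """
    C = np.array([_check_square(np.asarray(m, float)) for m in mats])
    if C.shape[0] == 0:
        raise ValueError("need at least one matrix")
    if C.shape[0] == 1:
        return C[0].copy()
    flat = C.reshape(C.shape[0], -1)
    scale = max(float(np.abs(flat).max()), np.finfo(float).tiny)
    U = flat.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(flat - U, axis=1)
        hit = d < 1e-14 * scale
        if hit.any():
            # Vardi-Zhang rule: move only if the residual pull exceeds the
            # multiplicity of the coincident data point(s).
            others = ~hit
            if not others.any():
                break
            r_vec = np.sum((flat[others] - U) / d[others, None], axis=0)
            r = np.linalg.norm(r_vec)
            eta = float(hit.sum())
            if r <= eta:
                break
            w = np.sum(1.0 / d[others])
            step = max(0.0, 1.0 - eta / r) * (r_vec / w)
            U_new = U + step
        else:
            w = 1.0 / d
            U_new = (w[:, None] * flat).sum(axis=0) / w.sum()
        if np.linalg.norm(U_new - U) < tol * scale:
            U = U_new
            break
        U = U_new
    M = U.reshape(C.shape[1], C.shape[2])
    return (M + M.T) / 2.0


def _sym_indices(c: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(c)
    return iu


def sym_to_vec(S: np.ndarray) -> np.ndarray:
    """Vectorise a symmetric matrix, off-diagonals scaled by sqrt(2).

    The scaling makes the Euclidean inner product of the vectors equal the
    Frobenius inner product of the matrices, so tangent-space PCA respects
    the manifold metric at the base point.
    """
    S = np.asarray(S, float)
    c = S.shape[0]
    i, j = np.triu_indices(c)
    v = S[i, j].copy()
    v[i != j] *= np.sqrt(2.0)
    return v


def vec_to_sym(v: np.ndarray, c: int) -> np.ndarray:
    """Inverse of :func:`sym_to_vec`."""
    i, j = np.triu_indices(c)
    vv = np.asarray(v, float).copy()
    vv[i != j] /= np.sqrt(2.0)
    S = np.zeros((c, c))
    S[i, j] = vv
    S[j, i] = vv
    return S


def pga(mats, base="karcher"):
    """Principal geodesic analysis of a set of SPD matrices.

    Tangent-space realisation (the Fletcher approximation): map every
    matrix to the tangent space at ``base`` with the log map, vectorise
    with :func:`sym_to_vec`, and eigendecompose the resulting covariance.
    Variance is squared Riemannian distance from the base along each
    direction; directions are returned as symmetric matrices, orthonormal
    in the tangent (Frobenius) inner product expressed through the
    whitened coordinates at ``base``.

    Parameters
    ----------
    mats : sequence of ndarray
        At least two SPD matrices.
    base : ndarray or "karcher"
        Base point; the token ``"karcher"`` uses the Karcher mean of
        ``mats``.

    Returns
    -------
    directions : list of ndarray
        Tangent directions (symmetric c x c), leading first.
    variances : ndarray
        Nonincreasing, nonnegative tangent variances.
    """
    mats = [regularize_spd(_check_spd(np.asarray(m, float))) for m in mats]
    if len(mats) < 2:
        raise ValueError("PGA needs at least two matrices")
    c = mats[0].shape[0]
    if isinstance(base, str):
        if base != "karcher":
            raise ValueError(f"unknown base token {base!r}")
        base_pt = karcher_mean(mats)
    else:
        base_pt = regularize_spd(_check_spd(np.asarray(base, float), "base"))

    # whitened tangent coordinates: S_i = logm(B^{-1/2} C_i B^{-1/2});
    # the affine-invariant inner product at B becomes Frobenius there.
    Bis = sym_inv_sqrt(base_pt)
    Bs = sym_sqrt(base_pt)
    vecs = np.array([
        sym_to_vec(sym_logm(regularize_spd(Bis @ C @ Bis))) for C in mats
    ])
    mean_vec = vecs.mean(axis=0)
    X = vecs - mean_vec
    cov = X.T @ X / len(mats)
    w, Q = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    Q = Q[:, order]
    directions = [Bs @ vec_to_sym(Q[:, k], c) @ Bs for k in range(Q.shape[1])]
    return directions, w


def sample_covariance_unbiased(X, regularize: bool = True) -> np.ndarray:
    """Unbiased per-segment covariance estimator ``X X^T / (t - 1)``.

    ``X`` may be an :class:`~rasr.segments.EEGSegment` or a channels x
    samples array with t >= 2 samples.  No mean is removed: the segments
    ASR sees are already high-pass filtered, and the estimator must match
    the calibration statistics which are likewise computed on raw outer
    products.
    """
    data = getattr(X, "data", X)
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("expected a channels x samples array")
    c, t = data.shape
    if t < 2:
        raise ValueError("need at least 2 samples for the unbiased estimator")
    U = data @ data.T / (t - 1)
    U = (U + U.T) / 2.0
    if regularize:
        U = regularize_spd(U)
    return U
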