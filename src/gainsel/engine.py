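"""Selection-index mathematics.

Three constructions of the index weights b for the score I = b'X:

* Smith–Hazel: b solves P b = G a for given economic values a, the classic
  maximum-correlation index.
* Desired gains, all traits constrained (m = n): b solves G b = Q.
* Desired gains on a subset (m < n): the restricted index
  b = P^-1 G* [G*' P^-1 G*]^-1 Q, with G* the n x m sub-matrix of G for the
  constrained traits. This is the minimum-variance index (argmin b' P b)
  whose expected responses hit Q exactly on the constrained traits; when
  every trait is constrained it reduces algebraically to G^-1 Q.

Around the weights: implied economic values a = G^-1 P b (inverting the
Smith–Hazel relation), correlated responses Q* = G b for all traits, and
the index standard deviation sigma_I = sqrt(b' P b), which under the
single-generation assumption equals the selection intensity required to
achieve Q.

All inversions are linear solves on symmetric factorizations, never
explicit inverses; condition numbers above 1e12 trigger a warning naming
the matrix (marker-estimated G for many traits from few genotypes is
routinely near-singular).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .core import GeneticParameters, TraitPanel

#: condition number above which a solve warns about near-singularity
COND_WARN = 1e12


class SingularMatrixError(np.linalg.LinAlgError):
    """A required covariance (sub-)matrix is singular or numerically rank-deficient."""


def _solve_sym(M: np.ndarray, rhs: np.ndarray, name: str) -> np.ndarray:
    """Solve M x = rhs for symmetric M with conditioning diagnostics."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1 / np.finfo(float).eps:
        raise SingularMatrixError(f"{name} is singular (condition number {cond:.3g})")
    if cond > COND_WARN:
        warnings.warn(
            f"{name} is ill-conditioned (condition number {cond:.3g}); "
            "solutions may be numerically unstable",
            stacklevel=3,
        )
    try:
        return scipy.linalg.solve(M, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - cond check first
        raise SingularMatrixError(f"{name} is singular") from exc


def score_index(b: np.ndarray, X: np.ndarray) -> np.ndarray | float:
    """Index score(s) I = b'X.

    ``X`` may be a single phenotype vector (returns a scalar) or an
    (individuals x traits) matrix (returns one score per row).
    """
    b = np.asarray(b, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        if X.shape[0] != b.shape[0]:
            raise ValueError(f"length mismatch: b has {b.shape[0]}, X has {X.shape[0]}")
        return float(b @ X)
    if X.shape[1] != b.shape[0]:
        raise ValueError(f"length mismatch: b has {b.shape[0]}, X has {X.shape[1]} columns")
    return X @ b


def smith_hazel_weights(params: GeneticParameters, a: np.ndarray) -> np.ndarray:
    """Index weights from economic values: solve P b = G a."""
    a = np.asarray(a, dtype=float)
    return np.atleast_1d(_solve_sym(params.P, params.G @ a, "P"))


def desired_gain_weights_full(params: GeneticParameters, Q: np.ndarray) -> np.ndarray:
    """Weights achieving desired gains on every trait: solve G b = Q."""
    Q = np.asarray(Q, dtype=float)
    return np.atleast_1d(_solve_sym(params.G, Q, "G"))


def restricted_gain_weights(
    params: GeneticParameters, Q: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Weights achieving desired gains Q on the ``mask`` subset of traits.

    b = P^-1 G* [G*' P^-1 G*]^-1 Q with G* = G[:, mask]; implemented as
    nested symmetric solves. The expected response G b equals Q exactly on
    the masked traits, and among all such weight vectors this one minimises
    the index variance b' P b.
    """
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    mask = np.asarray(mask, dtype=int)
    if Q.shape[0] != mask.shape[0]:
        raise ValueError(f"Q has {Q.shape[0]} entries but mask names {mask.shape[0]} traits")
    if mask.shape[0] > params.n:
        raise ValueError("more constrained traits than panel traits")
    G_star = params.G[:, mask]  # n x m
    Pinv_G_star = _solve_sym(params.P, G_star, "P")
    gram = G_star.T @ Pinv_G_star  # m x m, = G*' P^-1 G*
    try:
        alpha = _solve_sym(gram, Q, "G*' P^-1 G*")
    except SingularMatrixError as exc:
        raise SingularMatrixError(
            "desired gains unattainable/degenerate: G*' P^-1 G* is rank-deficient "
            "(constrained traits are genetically redundant)"
        ) from exc
    return np.atleast_1d(Pinv_G_star @ alpha)


def implied_economic_values(params: GeneticParameters, b: np.ndarray) -> np.ndarray:
    """Economic values consistent with weights b: solve G a = P b.

    Inverts the Smith–Hazel relation, so smith_hazel_weights(params, a)
    recovers b whenever G and P are invertible.
    """
    b = np.asarray(b, dtype=float)
    return np.atleast_1d(_solve_sym(params.G, params.P @ b, "G"))


def normalize_economic_values(a: np.ndarray, ref_index: int) -> np.ndarray:
    """Economic values as ratios to the reference trait (reference = 1)."""
    a = np.asarray(a, dtype=float)
    if a[ref_index] == 0:
        raise ZeroDivisionError(
            "reference trait has zero economic value; ratios are undefined"
        )
    return a / a[ref_index]


def format_ratio(r: float) -> str:
    """Print an economic-value ratio the way scenario tables do.

    Ratios of magnitude >= 10 are shown as integers, smaller ones with one
    decimal place. The unrounded ratio is always available upstream.
    """
    return f"{r:.0f}" if abs(r) >= 10 else f"{r:.1f}"


def correlated_responses(params: GeneticParameters, b: np.ndarray) -> np.ndarray:
    """Expected responses for all traits, Q* = G b.

    Valid as a per-generation response under the i = sigma_I assumption:
    the response in trait j to selection on I is i * cov(g_j, I) / sigma_I,
    which collapses to (G b)_j when i = sigma_I.
    """
    b = np.asarray(b, dtype=float)
    if b.shape[0] != params.n:
        raise ValueError(f"b has {b.shape[0]} entries for {params.n} traits")
    return params.G @ b


def index_sd_and_intensity(
    params: GeneticParameters, b: np.ndarray
) -> tuple[float, float]:
    """Index standard deviation sigma_I = sqrt(b' P b) and required intensity.

    Under the single-generation assumption the intensity needed to realise
    the desired gains equals sigma_I, so the pair (sigma_I, i) is returned
    with i = sigma_I. A negative quadratic form signals a non-PSD P.
    """
    b = np.asarray(b, dtype=float)
    q = float(b @ params.P @ b)
    if q < -1e-10 * max(1.0, float(np.abs(params.P).max())):
        raise ValueError("b' P b < 0: P is not positive semi-definite")
    sigma = float(np.sqrt(max(q, 0.0)))
    return sigma, sigma


def relative_change(Q_star: np.ndarray, panel: TraitPanel) -> np.ndarray:
    """Responses as percent of current means, 100 * Q*_j / mu_j."""
    Q_star = np.asarray(Q_star, dtype=float)
    if np.any(panel.means == 0):
        bad = [panel.names[j] for j in np.flatnonzero(panel.means == 0)]
        raise ZeroDivisionError(f"zero current mean for {bad}; relative change undefined")
    return 100.0 * Q_star / panel.means
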