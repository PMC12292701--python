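"""Marginal dependence measures between a feature block and a response block.

Every measure here maps a pair of aligned data blocks — an ``n x dx`` feature
block (one column per platform channel) and an ``n x q`` response block — to a
single dependence score in ``[0, 1]``.  Screening ranks features by these
scores, so only the *strength* of dependence matters: signed statistics
(Pearson, Kendall) are returned in absolute value.

Three measures handle genuinely multivariate blocks:

* :func:`distance_correlation` — the empirical distance correlation built from
  double-centered pairwise Euclidean distance matrices (the V-statistic with
  ``1/n**2`` normalisation).
* :func:`projection_correlation` — the largest absolute Pearson correlation
  between one-dimensional projections ``u'X`` and ``v'Y`` over unit vectors
  ``u, v``, approximated by maximising over a finite set of random directions
  (exact in the univariate case, where the only unit vectors are ``+-1``).
* :func:`wasserstein_dependence` — a Bures–Wasserstein dependence coefficient
  computed from the eigenvalues of the marginal and joint sample covariance
  matrices.  It is 0 when the sample cross-covariance vanishes and 1 at
  maximal coupling, and it avoids solving any optimal-transport problem.

The remaining measures (absolute Pearson, Pearson against response ranks,
Kendall's tau, distance correlation against response ranks) are the classical
univariate screening statistics used as baselines.

All measures require complete data; missing-value handling belongs upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau, rankdata

__all__ = [
    "PairwiseDistanceStructure",
    "CovarianceSpectrum",
    "ProjectionSet",
    "pearson_dependence",
    "rank_response_dependence",
    "kendall_dependence",
    "distance_correlation",
    "distance_correlation_rank_response",
    "projection_correlation",
    "wasserstein_dependence",
    "double_centered_distances",
    "covariance_spectrum",
    "draw_projection_set",
]

#: relative threshold below which covariance eigenvalues are clamped to zero
#: (sample covariance matrices are PSD only up to roundoff)
EIGENVALUE_CLAMP = 1e-12


class ConstantBlockWarning(UserWarning):
    """A data block has zero variance; the measure returns 0."""


def _as_block(data, name: str) -> np.ndarray:
    """Coerce to an (n, d) float array, rejecting non-finite values."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, np.newaxis]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-dimensional, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError(f"{name} needs at least 2 observations, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


def _paired_blocks(x, y, *, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    xb = _as_block(x, "x")
    yb = _as_block(y, "y")
    if xb.shape[0] != yb.shape[0]:
        raise ValueError(
            f"x and y must share the sample dimension: {xb.shape[0]} != {yb.shape[0]}"
        )
    if xb.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations, got {xb.shape[0]}")
    return xb, yb


def _require_univariate(xb: np.ndarray, yb: np.ndarray, measure: str) -> None:
    if xb.shape[1] != 1 or yb.shape[1] != 1:
        raise ValueError(
            f"{measure} is a univariate measure; got dx={xb.shape[1]}, q={yb.shape[1]}"
        )


def _abs_pearson(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    """|Pearson r| of two 1-d vectors; 0 with a warning when either is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            f"{measure}: zero-variance block, returning 0", ConstantBlockWarning,
            stacklevel=3,
        )
        return 0.0
    return float(min(abs(xc @ yc) / (sx * sy), 1.0))


# ---------------------------------------------------------------------------
# univariate baselines


def pearson_dependence(x, y) -> float:
    """Absolute Pearson correlation between two univariate blocks.

    The screening statistic of classical sure independence screening (SIS).
    """
    xb, yb = _paired_blocks(x, y)
    _require_univariate(xb, yb, "pearson_dependence")
    return _abs_pearson(xb[:, 0], yb[:, 0], "pearson_dependence")


def rank_response_dependence(x, y) -> float:
    """Absolute Pearson correlation between ``x`` and the ranks of ``y``.

    The rank-and-screen (SIRS-style) statistic; ties in ``y`` receive
    average ranks.
    """
    xb, yb = _paired_blocks(x, y)
    _require_univariate(xb, yb, "rank_response_dependence")
    ranks = rankdata(yb[:, 0], method="average")
    return _abs_pearson(xb[:, 0], ranks, "rank_response_dependence")


def kendall_dependence(x, y) -> float:
    """Absolute Kendall's tau (tie-adjusted tau-b) between univariate blocks.

    The robust rank correlation screening (RRCS) statistic.
    """
    xb, yb = _paired_blocks(x, y)
    _require_univariate(xb, yb, "kendall_dependence")
    tau = kendalltau(xb[:, 0], yb[:, 0]).statistic
    if np.isnan(tau):
        warnings.warn(
            "kendall_dependence: all-tied block, returning 0", ConstantBlockWarning,
            stacklevel=2,
        )
        return 0.0
    return float(min(abs(tau), 1.0))


# ---------------------------------------------------------------------------
# distance correlation


@dataclass(frozen=True)
class PairwiseDistanceStructure:
    """Pairwise Euclidean distances of one block and their double-centering.

    ``centered[k, l] = a[k, l] - row_means[k] - col_means[l] + grand_mean``;
    every row and column of ``centered`` sums to zero.
    """

    a: np.ndarray
    centered: np.ndarray
    row_means: np.ndarray
    col_means: np.ndarray
    grand_mean: float


def double_centered_distances(block) -> PairwiseDistanceStructure:
    """Build the double-centered Euclidean distance matrix of one block."""
    b = _as_block(block, "block")
    a = cdist(b, b)
    row_means = a.mean(axis=1)
    col_means = a.mean(axis=0)
    grand_mean = float(a.mean())
    centered = a - row_means[:, np.newaxis] - col_means[np.newaxis, :] + grand_mean
    return PairwiseDistanceStructure(a, centered, row_means, col_means, grand_mean)


def distance_correlation(x, y) -> float:
    """Empirical distance correlation between two (possibly multivariate) blocks.

    Computed from the double-centered pairwise distance matrices ``A`` and
    ``B`` as ``sqrt( mean(A*B) / sqrt(mean(A*A) * mean(B*B)) )`` with all
    means over the full ``n x n`` grid.  Returns 0 when either block is
    constant (its distance variance vanishes).
    """
    xb, yb = _paired_blocks(x, y, min_n=3)
    A = double_centered_distances(xb).centered
    B = double_centered_distances(yb).centered
    dvar_x = float((A * A).mean())
    dvar_y = float((B * B).mean())
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    dcov2 = float((A * B).mean())
    r2 = dcov2 / np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(max(r2, 0.0)))


def distance_correlation_rank_response(x, y) -> float:
    """Distance correlation between ``x`` and the componentwise ranks of ``y``.

    The robust variant (DC-RoSIS style): replacing the scalar response by its
    average ranks makes the score invariant to strictly increasing response
    transforms.
    """
    xb, yb = _paired_blocks(x, y, min_n=3)
    ranked = np.column_stack(
        [rankdata(yb[:, j], method="average") for j in range(yb.shape[1])]
    )
    return distance_correlation(xb, ranked)


# ---------------------------------------------------------------------------
# projection correlation


@dataclass(frozen=True)
class ProjectionSet:
    """Finite sets of unit projection directions for the two blocks."""

    u_directions: np.ndarray  # (dx, K_u), unit columns
    v_directions: np.ndarray  # (q, K_v), unit columns
    seed: int | None = None

    def __post_init__(self):
        for name, dirs in (("u", self.u_directions), ("v", self.v_directions)):
            if dirs.ndim != 2 or dirs.shape[1] < 1:
                raise ValueError(f"{name}_directions must be a (dim, K>=1) array")
            norms = np.linalg.norm(dirs, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError(f"{name}_directions must have unit columns")


def _unit_directions(dim: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k unit vectors drawn uniformly on the (dim-1)-sphere, as columns."""
    if dim == 1:
        return np.ones((1, 1))
    v = rng.standard_normal((dim, k))
    norms = np.linalg.norm(v, axis=0)
    # resample the (measure-zero) degenerate draws
    while np.any(norms == 0.0):
        bad = norms == 0.0
        v[:, bad] = rng.standard_normal((dim, int(bad.sum())))
        norms = np.linalg.norm(v, axis=0)
    return v / norms


def draw_projection_set(
    dx: int, q: int, n_directions: int = 100, seed=None
) -> ProjectionSet:
    """Sample uniform unit directions for both blocks.

    Univariate sides get the single direction ``[1]`` (the supremum over
    ``+-1`` is attained exactly there because the score is an absolute
    correlation).
    """
    rng = np.random.default_rng(seed)
    u = _unit_directions(dx, n_directions, rng)
    v = _unit_directions(q, n_directions, rng)
    return ProjectionSet(u, v, seed=seed if isinstance(seed, int) else None)


def _standardize_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns to unit norm; flag zero-variance columns."""
    c = mat - mat.mean(axis=0, keepdims=True)
    norms = np.sqrt((c * c).sum(axis=0))
    ok = norms > 0.0
    c[:, ok] /= norms[ok]
    c[:, ~ok] = 0.0
    return c, ok


def projection_correlation(x, y, directions: ProjectionSet | None = None,
                           n_directions: int = 100, seed=None) -> float:
    """Maximum absolute Pearson correlation over projections of the blocks.

    Approximates ``sup_{|u|=|v|=1} |Corr(u'X, v'Y)|`` by maximising over a
    finite direction set.  With both blocks univariate the supremum is exact
    (``|Pearson(x, y)|``); degenerate projections (zero variance along a
    direction) contribute 0.

    Parameters
    ----------
    directions
        Pre-drawn :class:`ProjectionSet`; if omitted, ``n_directions``
        directions per side are drawn from ``seed``.
    """
    xb, yb = _paired_blocks(x, y)
    dx, q = xb.shape[1], yb.shape[1]
    if dx == 1 and q == 1:
        xc = xb[:, 0] - xb[:, 0].mean()
        yc = yb[:, 0] - yb[:, 0].mean()
        sx, sy = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
        if sx == 0.0 or sy == 0.0:
            return 0.0
        return float(min(abs(xc @ yc) / (sx * sy), 1.0))
    if directions is None:
        directions = draw_projection_set(dx, q, n_directions, seed)
    if directions.u_directions.shape[0] != dx or directions.v_directions.shape[0] != q:
        raise ValueError("projection directions drawn for the wrong dimensions")
    px, _ = _standardize_columns(xb @ directions.u_directions)
    py, _ = _standardize_columns(yb @ directions.v_directions)
    corr = px.T @ py
    return float(min(np.abs(corr).max(initial=0.0), 1.0))


# ---------------------------------------------------------------------------
# Wasserstein dependence


@dataclass(frozen=True)
class CovarianceSpectrum:
    """Sample covariance matrices of two blocks and their eigenvalues.

    Eigenvalues are stored in descending order with negatives below the
    clamping tolerance set to zero; ``max_dim`` is ``max(dx, q)``.
    """

    sigma_x: np.ndarray
    sigma_y: np.ndarray
    sigma_joint: np.ndarray
    lambda_x: np.ndarray = field(repr=False)
    lambda_y: np.ndarray = field(repr=False)
    lambda_joint: np.ndarray = field(repr=False)
    max_dim: int = 0


def _clamped_eigvalsh(sym: np.ndarray) -> np.ndarray:
    """Descending eigenvalues with tiny negatives clamped to zero."""
    lam = np.linalg.eigvalsh(sym)[::-1].copy()
    top = lam[0] if lam.size else 0.0
    lam[lam < EIGENVALUE_CLAMP * max(top, 0.0)] = 0.0
    np.clip(lam, 0.0, None, out=lam)
    return lam


def covariance_spectrum(x, y) -> CovarianceSpectrum:
    """Covariance matrices (divisor ``n - 1``) and spectra of a block pair."""
    xb, yb = _paired_blocks(x, y)
    dx, q = xb.shape[1], yb.shape[1]
    joint = np.cov(np.hstack([xb, yb]), rowvar=False, ddof=1)
    joint = np.atleast_2d(joint)
    sigma_x = joint[:dx, :dx]
    sigma_y = joint[dx:, dx:]
    return CovarianceSpectrum(
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        sigma_joint=joint,
        lambda_x=_clamped_eigvalsh(sigma_x),
        lambda_y=_clamped_eigvalsh(sigma_y),
        lambda_joint=_clamped_eigvalsh(joint),
        max_dim=max(dx, q),
    )


def wasserstein_dependence(x, y) -> float:
    """Bures–Wasserstein dependence coefficient between two blocks.

    With ``l_X``, ``l_Y`` the descending eigenvalues of the marginal sample
    covariances and ``l`` those of the joint covariance, the coefficient is

    ``D1 = (sum sqrt(l_X) + sum sqrt(l_Y) - sum sqrt(l))
          / (sum sqrt(l_X) + sum sqrt(l_Y) - sum_{j<=max(dx,q)} sqrt(l_X[j] + l_Y[j]))``

    where the shorter eigenvalue list is zero-padded for the denominator
    pairing.  ``D1`` is 0 when the blocks are (sample-)uncorrelated — the
    joint spectrum is then the union of the marginal spectra — and 1 at
    maximal coupling.  It is invariant under common rescaling of all data,
    so the ``n - 1`` covariance divisor is immaterial; returns 0 with a
    warning when the denominator degenerates (e.g. both blocks constant).
    The result is clamped to ``[0, 1]``.
    """
    spec = covariance_spectrum(x, y)
    m = spec.max_dim
    lx = np.zeros(m)
    lx[: spec.lambda_x.size] = spec.lambda_x
    ly = np.zeros(m)
    ly[: spec.lambda_y.size] = spec.lambda_y
    marginal_mass = float(np.sqrt(spec.lambda_x).sum() + np.sqrt(spec.lambda_y).sum())
    numerator = marginal_mass - float(np.sqrt(spec.lambda_joint).sum())
    denominator = marginal_mass - float(np.sqrt(lx + ly).sum())
    if denominator <= EIGENVALUE_CLAMP * max(marginal_mass, 1.0):
        warnings.warn(
            "wasserstein_dependence: degenerate denominator, returning 0",
            ConstantBlockWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(numerator / denominator, 0.0, 1.0))
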