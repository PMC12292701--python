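"""Marginal screening: score every feature, rank, select top-[n/log n], intersect.

A predictor is a ``d x n x p`` :class:`FeatureArray` — ``d`` platforms (e.g.
copy number, mRNA, methylation), ``n`` samples, ``p`` features — so each
feature ``j`` contributes an ``n x d`` block.  :func:`screen` applies one
dependence measure marginally to every feature block against the full
``n x q`` response, ranks features by descending score (ties broken by
ascending feature index, so results are reproducible), and selects the top
``s = floor(n / log n)`` features.  :func:`consensus` intersects the top sets
of several methods.

Features are streamed in chunks so memory scales with the chunk size, not
with ``p``; each registered measure provides a vectorised chunk kernel whose
output matches the corresponding scalar function in
:mod:`wdscreen.measures` (tested to near machine precision).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from . import measures
from .measures import EIGENVALUE_CLAMP, draw_projection_set

__all__ = [
    "FeatureArray",
    "ScreeningResult",
    "MeasureCapabilityError",
    "cutoff_size",
    "screen",
    "select_top",
    "consensus",
    "true_predictor_ranks",
    "available_measures",
    "MEASURE_NAMES",
]

logger = logging.getLogger(__name__)

#: registry key -> display name used in output headers
MEASURE_NAMES = {
    "sis": "SIS",
    "sirs": "SIRS",
    "rrcs": "RRCS",
    "dcsis": "DC-SIS",
    "dcrosis": "DC-RoSIS",
    "pcscreen": "PC-Screen",
    "wdscreen": "WD-Screen",
}

#: measures restricted to one platform channel and a scalar response
UNIVARIATE_ONLY = frozenset({"sis", "sirs", "rrcs", "dcrosis"})


class MeasureCapabilityError(ValueError):
    """A measure cannot handle the requested (d, q) dimensions."""


def available_measures() -> list[str]:
    return sorted(MEASURE_NAMES)


def cutoff_size(n: int) -> int:
    """Conventional screening-set size ``floor(n / ln n)``.

    Examples: n=200 -> 37, n=230 -> 42, n=185 -> 35.
    """
    n = int(n)
    if n < 3:
        raise ValueError(f"cutoff_size requires n >= 3, got {n}")
    return int(math.floor(n / math.log(n)))


@dataclass
class FeatureArray:
    """``d x n x p`` predictor container (``d = 1`` degenerates to a matrix)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str] | None = None
    platform_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # accept an n x p matrix for d = 1
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise ValueError(f"values must be d x n x p, got shape {self.values.shape}")
        d, n, p = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for p={p}")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if self.sample_ids is not None:
            if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
                raise ValueError("sample_ids must be unique and of length n")
        if self.platform_names is not None:
            if len(self.platform_names) != d or len(set(self.platform_names)) != d:
                raise ValueError("platform_names must be unique and of length d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureArray contains missing or non-finite values")

    @property
    def n_platforms(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @classmethod
    def from_matrix(cls, matrix, feature_ids, sample_ids=None,
                    platform_name: str = "platform") -> "FeatureArray":
        """Wrap a single ``n x p`` matrix as a one-platform array."""
        m = np.asarray(matrix, dtype=float)
        return cls(m[np.newaxis], list(feature_ids), sample_ids, [platform_name])

    def feature_block(self, j: int) -> np.ndarray:
        """The ``n x d`` block of feature ``j``."""
        return self.values[:, :, j].T


@dataclass
class ScreeningResult:
    """Per-feature scores and ranks plus the selected top set of one method."""

    method: str
    feature_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    cutoff_s: int
    selected: list[str] = field(default_factory=list)

    @property
    def method_name(self) -> str:
        return MEASURE_NAMES.get(self.method, self.method)

    def rank_of(self, feature_id: str) -> int:
        return int(self.ranks[self.feature_ids.index(feature_id)])

    def to_frame(self) -> pd.DataFrame:
        sel = np.zeros(len(self.feature_ids), dtype=int)
        sel[self.ranks <= self.cutoff_s] = 1
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "score": self.scores,
                "rank": self.ranks,
                "selected": sel,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chunk kernels: each maps (chunk, n, d) blocks + prepared response context
# to a vector of scores, matching the scalar functions in `measures`.


def _rank_matrix(y: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [rankdata(y[:, j], method="average") for j in range(y.shape[1])]
    )


def _unit_rows(xc2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns of an (n, c) matrix and scale to unit norm."""
    c = xc2d - xc2d.mean(axis=0, keepdims=True)
    norms = np.sqrt((c * c).sum(axis=0))
    ok = norms > 0.0
    c[:, ok] /= norms[ok]
    c[:, ~ok] = 0.0
    return c, ok


class _PearsonKernel:
    """SIS: absolute Pearson correlation (univariate)."""

    key = "sis"
    rank_response = False

    def supports(self, d: int, q: int) -> bool:
        return d == 1 and q == 1

    def prepare(self, y: np.ndarray, seed) -> dict:
        yv = _rank_matrix(y)[:, 0] if self.rank_response else y[:, 0]
        yc = yv - yv.mean()
        ny = float(np.sqrt(yc @ yc))
        return {"yc": yc, "ny": ny}

    def score_chunk(self, blocks: np.ndarray, ctx: dict) -> np.ndarray:
        x = blocks[:, :, 0].T  # (n, c)
        xc, ok = _unit_rows(x)
        if ctx["ny"] == 0.0:
            return np.zeros(blocks.shape[0])
        scores = np.abs(xc.T @ ctx["yc"]) / ctx["ny"]
        scores[~ok] = 0.0
        return np.minimum(scores, 1.0)


class _RankPearsonKernel(_PearsonKernel):
    """SIRS: Pearson correlation against response ranks."""

    key = "sirs"
    rank_response = True


class _KendallKernel:
    """RRCS: absolute Kendall tau-b (univariate)."""

    key = "rrcs"

    def supports(self, d: int, q: int) -> bool:
        return d == 1 and q == 1

    def prepare(self, y: np.ndarray, seed) -> dict:
        return {"y": y[:, 0]}

    def score_chunk(self, blocks: np.ndarray, ctx: dict) -> np.ndarray:
        yv = ctx["y"]
        out = np.empty(blocks.shape[0])
        for i in range(blocks.shape[0]):
            tau = kendalltau(blocks[i, :, 0], yv).statistic
            out[i] = 0.0 if np.isnan(tau) else min(abs(tau), 1.0)
        return out


try:  # compiled inner loop; the numpy chunk path below is the fallback
    from numba import njit

    @njit(cache=True)
    def _dcor_stats_jit(blocks, B):  # pragma: no cover - exercised via wrapper
        c, n, d = blocks.shape
        dcov2 = np.zeros(c)
        dvar = np.zeros(c)
        for f in range(c):
            row = np.zeros(n)
            sq_total = 0.0
            num = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    s = 0.0
                    for k in range(d):
                        t = blocks[f, i, k] - blocks[f, j, k]
                        s += t * t
                    dist = np.sqrt(s)
                    row[i] += dist
                    row[j] += dist
                    sq_total += 2.0 * s
                    num += 2.0 * dist * B[i, j]
            grand = row.sum() / (n * n)
            rm2 = 0.0
            for i in range(n):
                rm2 += (row[i] / n) ** 2
            dvar[f] = sq_total / (n * n) - 2.0 * rm2 / n + grand * grand
            dcov2[f] = num / (n * n)
        return dcov2, dvar

except ImportError:  # pragma: no cover
    _dcor_stats_jit = None


class _DistanceCorrelationKernel:
    """DC-SIS: distance correlation, any (d, q).

    The chunk kernel never materialises the double-centered matrices ``A``:
    because double-centering is an orthogonal projection of the distance
    matrix, ``mean(A*B) = mean(a*B)`` whenever ``B`` is already centered, and
    ``mean(A*A) = mean(a^2) - 2*mean(rowmeans(a)^2) + grandmean(a)^2``.
    A compiled single-pass loop exploits the symmetry of the distance matrix;
    without numba the same statistics come from the batched Gram matrix.
    """

    key = "dcsis"
    rank_response = False

    def supports(self, d: int, q: int) -> bool:
        return True

    def prepare(self, y: np.ndarray, seed) -> dict:
        yv = _rank_matrix(y) if self.rank_response else y
        B = measures.double_centered_distances(yv).centered
        return {"B": B, "dvar_y": float((B * B).mean())}

    def score_chunk(self, blocks: np.ndarray, ctx: dict) -> np.ndarray:
        c, n, d = blocks.shape
        if _dcor_stats_jit is not None:
            dcov2, dvar_x = _dcor_stats_jit(
                np.ascontiguousarray(blocks), np.ascontiguousarray(ctx["B"])
            )
        else:
            gram = np.matmul(blocks, np.swapaxes(blocks, 1, 2))
            norms = np.einsum("cii->ci", gram)
            sq = norms[:, :, np.newaxis] + norms[:, np.newaxis, :] - 2.0 * gram
            np.maximum(sq, 0.0, out=sq)  # roundoff can leave tiny negatives
            mean_sq = sq.mean(axis=(1, 2))
            a = np.sqrt(sq, out=sq)
            row = a.mean(axis=2)
            grand = row.mean(axis=1)
            dvar_x = mean_sq - 2.0 * (row * row).mean(axis=1) + grand * grand
            dcov2 = np.einsum("cij,ij->c", a, ctx["B"], optimize=True) / (n * n)
        out = np.zeros(c)
        ok = (dvar_x > 0.0) & (ctx["dvar_y"] > 0.0)
        out[ok] = np.sqrt(
            np.maximum(dcov2[ok] / np.sqrt(dvar_x[ok] * ctx["dvar_y"]), 0.0)
        )
        return out


class _RankDistanceCorrelationKernel(_DistanceCorrelationKernel):
    """DC-RoSIS: distance correlation against response ranks (univariate)."""

    key = "dcrosis"
    rank_response = True

    def supports(self, d: int, q: int) -> bool:
        return d == 1 and q == 1


class _ProjectionKernel:
    """PC-Screen: max |Pearson| over sampled unit projection directions."""

    key = "pcscreen"

    def __init__(self, n_directions: int = 100):
        self.n_directions = int(n_directions)

    def supports(self, d: int, q: int) -> bool:
        return True

    def prepare(self, y: np.ndarray, seed) -> dict:
        q = y.shape[1]
        # d is bound at screen() time via ctx["dirs"] lazily; store pieces
        return {"y": y, "q": q, "seed": seed, "dirs": None}

    def bind_dimensions(self, d: int, ctx: dict) -> None:
        dirs = draw_projection_set(d, ctx["q"], self.n_directions, ctx["seed"])
        py, _ = _unit_rows(ctx["y"] @ dirs.v_directions)
        ctx["dirs"] = dirs
        ctx["py"] = py

    def score_chunk(self, blocks: np.ndarray, ctx: dict) -> np.ndarray:
        c, n, d = blocks.shape
        if ctx["dirs"] is None:
            self.bind_dimensions(d, ctx)
        u = ctx["dirs"].u_directions  # (d, Ku)
        px = np.matmul(blocks, u)  # (c, n, Ku)
        px -= px.mean(axis=1, keepdims=True)
        norms = np.sqrt((px * px).sum(axis=1, keepdims=True))
        np.divide(px, norms, out=px, where=norms > 0.0)
        px[np.broadcast_to(norms == 0.0, px.shape)] = 0.0
        corr = np.matmul(np.swapaxes(px, 1, 2), ctx["py"])  # (c, Ku, Kv)
        return np.minimum(np.abs(corr).max(axis=(1, 2), initial=0.0), 1.0)


class _WassersteinKernel:
    """WD-Screen: Bures–Wasserstein dependence from covariance eigenvalues."""

    key = "wdscreen"

    def supports(self, d: int, q: int) -> bool:
        return True

    def prepare(self, y: np.ndarray, seed) -> dict:
        n, q = y.shape
        yc = y - y.mean(axis=0, keepdims=True)
        syy = (yc.T @ yc) / (n - 1)
        lam_y = measures._clamped_eigvalsh(syy)
        return {"yc": yc, "syy": syy, "lam_y": lam_y}

    def score_chunk(self, blocks: np.ndarray, ctx: dict) -> np.ndarray:
        c, n, d = blocks.shape
        q = ctx["yc"].shape[1]
        xc = blocks - blocks.mean(axis=1, keepdims=True)
        sxx = np.einsum("cni,cnj->cij", xc, xc, optimize=True) / (n - 1)
        sxy = np.einsum("cni,nj->cij", xc, ctx["yc"], optimize=True) / (n - 1)
        joint = np.empty((c, d + q, d + q))
        joint[:, :d, :d] = sxx
        joint[:, :d, d:] = sxy
        joint[:, d:, :d] = np.swapaxes(sxy, 1, 2)
        joint[:, d:, d:] = ctx["syy"]
        lam_x = self._clamped_batch(np.linalg.eigvalsh(sxx))
        lam_joint = self._clamped_batch(np.linalg.eigvalsh(joint))
        lam_y = ctx["lam_y"]
        m = max(d, q)
        lx = np.zeros((c, m))
        lx[:, :d] = lam_x
        ly = np.zeros(m)
        ly[:q] = lam_y
        marginal = np.sqrt(lam_x).sum(axis=1) + np.sqrt(lam_y).sum()
        numer = marginal - np.sqrt(lam_joint).sum(axis=1)
        denom = marginal - np.sqrt(lx + ly[np.newaxis, :]).sum(axis=1)
        out = np.zeros(c)
        ok = denom > EIGENVALUE_CLAMP * np.maximum(marginal, 1.0)
        out[ok] = np.clip(numer[ok] / denom[ok], 0.0, 1.0)
        return out

    @staticmethod
    def _clamped_batch(lam: np.ndarray) -> np.ndarray:
        """Ascending eigvalsh output -> descending, tiny negatives clamped."""
        lam = lam[..., ::-1].copy()
        top = np.maximum(lam[..., :1], 0.0)
        lam[lam < EIGENVALUE_CLAMP * top] = 0.0
        return np.clip(lam, 0.0, None)


_KERNELS = {
    "sis": _PearsonKernel,
    "sirs": _RankPearsonKernel,
    "rrcs": _KendallKernel,
    "dcsis": _DistanceCorrelationKernel,
    "dcrosis": _RankDistanceCorrelationKernel,
    "pcscreen": _ProjectionKernel,
    "wdscreen": _WassersteinKernel,
}


def _resolve_measure(measure, n_directions: int):
    if isinstance(measure, str):
        key = measure.lower()
        if key not in _KERNELS:
            raise MeasureCapabilityError(
                f"unknown measure {measure!r}; registered: {', '.join(available_measures())}"
            )
        if key == "pcscreen":
            return _KERNELS[key](n_directions=n_directions)
        return _KERNELS[key]()
    return measure


def _as_response(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, np.newaxis]
    if arr.ndim != 2:
        raise ValueError(f"response must be n or n x q, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("response contains missing or non-finite values")
    return arr


def screen(x: FeatureArray, y, measure, *, cutoff: int | None = None,
           chunk_size: int = 512, seed=None, n_directions: int = 100) -> ScreeningResult:
    """Score all features with one measure, rank, and select the top set.

    Parameters
    ----------
    x
        ``d x n x p`` predictor array.
    y
        ``n x q`` response (1-d input treated as ``q = 1``).
    measure
        Registry key (``sis``, ``sirs``, ``rrcs``, ``dcsis``, ``dcrosis``,
        ``pcscreen``, ``wdscreen``) or a kernel instance.
    cutoff
        Selection-set size; defaults to :func:`cutoff_size` of ``n``.
    chunk_size
        Features scored per vectorised batch; memory is proportional to
        ``chunk_size * n**2`` for the distance-based measures.
    seed
        Source of randomness for direction sampling (PC-Screen only).
    """
    kernel = _resolve_measure(measure, n_directions)
    yv = _as_response(y)
    d, n, p = x.values.shape
    if yv.shape[0] != n:
        raise ValueError(f"response has {yv.shape[0]} samples, predictors have {n}")
    if not kernel.supports(d, yv.shape[1]):
        raise MeasureCapabilityError(
            f"measure {MEASURE_NAMES.get(kernel.key, kernel.key)!r} cannot handle "
            f"d={d} platforms with q={yv.shape[1]} response dimensions "
            "(univariate baselines require d=1, q=1)"
        )
    ctx = kernel.prepare(yv, seed)
    scores = np.empty(p)
    logged = 0
    for start in range(0, p, chunk_size):
        stop = min(start + chunk_size, p)
        blocks = np.ascontiguousarray(x.values[:, :, start:stop].transpose(2, 1, 0))
        scores[start:stop] = kernel.score_chunk(blocks, ctx)
        if stop - logged >= 1000:
            logger.info("%s: scored %d/%d features", kernel.key, stop, p)
            logged = stop
    order = np.lexsort((np.arange(p), -scores))  # ties -> ascending feature index
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    s = cutoff_size(n) if cutoff is None else int(cutoff)
    if not 1 <= s:
        raise ValueError(f"cutoff must be >= 1, got {s}")
    s_eff = min(s, p)
    selected = [x.feature_ids[j] for j in order[:s_eff]]
    return ScreeningResult(
        method=getattr(kernel, "key", str(measure)),
        feature_ids=list(x.feature_ids),
        scores=scores,
        ranks=ranks,
        cutoff_s=s,
        selected=selected,
    )


def select_top(result: ScreeningResult, s: int) -> list[str]:
    """The ``min(s, p)`` strongest feature ids, ordered by rank."""
    p = len(result.feature_ids)
    if not 1 <= s <= p:
        raise ValueError(f"s must be in [1, {p}], got {s}")
    order = np.argsort(result.ranks)
    return [result.feature_ids[j] for j in order[:s]]


def consensus(results: list[ScreeningResult], s: int) -> list[str]:
    """Intersection of each method's top-``s`` set, in feature-index order."""
    if not results:
        raise ValueError("consensus requires at least one ScreeningResult")
    universe = results[0].feature_ids
    for r in results[1:]:
        if r.feature_ids != universe:
            raise ValueError("all results must share the same feature universe")
    common = set(select_top(results[0], s))
    for r in results[1:]:
        common &= set(select_top(r, s))
    return [f for f in universe if f in common]


def true_predictor_ranks(result: ScreeningResult, truth) -> tuple[dict[str, int], int]:
    """Ranks of the true features and the minimum model size ``S``.

    ``S`` is the largest rank among the true predictors: the smallest top set
    that contains them all.
    """
    truth = [str(t) for t in truth]
    index = {f: i for i, f in enumerate(result.feature_ids)}
    missing = [t for t in truth if t not in index]
    if missing:
        raise KeyError(f"unknown true predictor ids: {missing}")
    ranks = {t: int(result.ranks[index[t]]) for t in truth}
    return ranks, max(ranks.values())
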