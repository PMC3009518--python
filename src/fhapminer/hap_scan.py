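"""Similarity clustering and association testing of scored founder haplotypes.

The scan slides a window across the markers.  At each focal marker the
windowed haplotype segments are compared with a position-weighted similarity
S = w_L * L + w_N * N, where N counts matching alleles inside the window and
L is the length of the maximal run of consecutive matches containing the
focal position (0 when the focal alleles differ).  Segments are grouped with
a density-based (DBSCAN) clustering under the distance d = S_max - S; each
cluster is tested with a Q-score, a Welch two-sample t statistic comparing
the phenotype scores of the cluster against the rest of the sample, and the
largest |Q| cluster becomes the marker's result.  Family-wise significance
uses either Bonferroni over markers or a permutation null of the
genome-wide max |Q| obtained by shuffling scores against haplotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN

from .founder_score import ScoredFounderHaplotype


@dataclass
class SimilarityParams:
    """Window length (in markers) and the two similarity weights.

    Odd windows are symmetric around the focal marker; an even window takes
    the extra marker on the right.  Windows are clipped at the chromosome
    ends, never padded.
    """

    window: int = 1
    w_len: float = 1.0   # weight of the shared-segment length term
    w_count: float = 1.0  # weight of the matching-allele count term

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be an integer >= 1")
        if self.w_len < 0 or self.w_count < 0 or (self.w_len == 0 and self.w_count == 0):
            raise ValueError("weights must be >= 0 and not both 0")


@dataclass
class DensityParams:
    """DBSCAN controls.

    ``min_pts`` defaults to max(2, ceil(0.05 n)).  The reachability radius
    is ``eps`` (a distance) when given, else derived from
    ``min_similarity_frac``: two segments are neighbours when their
    similarity is at least that fraction of the self-similarity maximum.
    """

    min_pts: int | None = None
    eps: float | None = None
    min_similarity_frac: float = 0.8

    def resolve(self, n: int, s_max: float) -> tuple[int, float]:
        min_pts = self.min_pts if self.min_pts is not None else max(2, math.ceil(0.05 * n))
        eps = self.eps if self.eps is not None else (1.0 - self.min_similarity_frac) * s_max
        return min_pts, eps


@dataclass
class ClusterResult:
    marker: int  # 0-based focal marker
    members: tuple[int, ...]  # indices into the pooled score list
    q: float
    p_raw: float
    p_adjusted: float


@dataclass
class ScanResult:
    alpha: float
    correction: str
    best: list[ClusterResult | None]  # one entry per marker

    @property
    def significant(self) -> list[bool]:
        return [
            r is not None and r.p_adjusted <= self.alpha for r in self.best
        ]

    @property
    def any_significant(self) -> bool:
        return any(self.significant)

    def p_values(self) -> list[float]:
        """Per-marker adjusted p (1.0 where no cluster formed)."""
        return [1.0 if r is None else r.p_adjusted for r in self.best]

    def raw_p_values(self) -> list[float]:
        return [1.0 if r is None else r.p_raw for r in self.best]


# ---------------------------------------------------------------------------
# similarity


def _window_bounds(focal: int, n_markers: int, window: int) -> tuple[int, int]:
    return max(0, focal - (window - 1) // 2), min(n_markers, focal + window // 2 + 1)


def similarity(
    h1: Sequence[int], h2: Sequence[int], focal: int, params: SimilarityParams
) -> float:
    """Position-weighted similarity of two haplotypes around a focal marker."""
    if len(h1) != len(h2):
        raise ValueError("haplotypes differ in length")
    if not 0 <= focal < len(h1):
        raise ValueError("focal marker out of bounds")
    lo, hi = _window_bounds(focal, len(h1), params.window)
    match = [h1[i] == h2[i] for i in range(lo, hi)]
    n = sum(match)
    f = focal - lo
    if not match[f]:
        run = 0
    else:
        run = 1
        i = f - 1
        while i >= 0 and match[i]:
            run += 1
            i -= 1
        i = f + 1
        while i < len(match) and match[i]:
            run += 1
            i += 1
    return params.w_len * run + params.w_count * n


def max_similarity(focal: int, n_markers: int, params: SimilarityParams) -> float:
    """Self-similarity of an identical pair at this focal marker (window may
    be clipped at the chromosome ends)."""
    lo, hi = _window_bounds(focal, n_markers, params.window)
    w_eff = hi - lo
    return (params.w_len + params.w_count) * w_eff


def _pairwise_similarity(
    haps: np.ndarray, focal: int, params: SimilarityParams
) -> np.ndarray:
    """n x n similarity matrix of windowed segments around ``focal``."""
    n, n_markers = haps.shape
    lo, hi = _window_bounds(focal, n_markers, params.window)
    seg = haps[:, lo:hi]
    f = focal - lo
    match = seg[:, None, :] == seg[None, :, :]  # n x n x w
    count = match.sum(axis=2)
    left = np.cumprod(match[:, :, f::-1], axis=2).sum(axis=2)
    right = np.cumprod(match[:, :, f:], axis=2).sum(axis=2)
    run = left + right - match[:, :, f].astype(np.int64)
    return params.w_len * run + params.w_count * count


# ---------------------------------------------------------------------------
# clustering


def cluster(
    haplotypes: Sequence[Sequence[int]] | np.ndarray,
    focal: int,
    params: SimilarityParams,
    density: DensityParams | None = None,
) -> list[list[int]]:
    """Density-based clusters of windowed haplotype segments.

    Returns member-index lists ordered by first appearance; noise points
    belong to no cluster.  Zero clusters is a valid outcome.
    """
    haps = np.asarray(haplotypes, dtype=np.int64)
    if haps.ndim != 2 or haps.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    density = density or DensityParams()
    s = _pairwise_similarity(haps, focal, params)
    s_max = max_similarity(focal, haps.shape[1], params)
    return _cluster_from_similarity(s, s_max, density)


def _cluster_from_similarity(
    s: np.ndarray, s_max: float, density: DensityParams
) -> list[list[int]]:
    n = s.shape[0]
    min_pts, eps = density.resolve(n, s_max)
    if min_pts > n:
        return []
    d = np.maximum(s_max - s, 0.0)
    np.fill_diagonal(d, 0.0)
    # sklearn requires eps > 0; an exact-match radius (eps = 0) is expressed
    # as an epsilon far below the similarity weight resolution
    labels = (
        DBSCAN(eps=max(eps, 1e-12), min_samples=min_pts, metric="precomputed")
        .fit(d)
        .labels_
    )
    out: list[list[int]] = []
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in seen:
            seen[lab] = len(out)
            out.append([])
        out[seen[lab]].append(i)
    return out


# ---------------------------------------------------------------------------
# Q-score


def q_score(
    cluster_scores: Sequence[float], all_scores: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t statistic (cluster vs complement) and two-sided p.

    The complement is the full sample minus the cluster (by counts and sums,
    so duplicate score values need no identity bookkeeping).  Both groups
    need at least two members so both variances are estimable; smaller
    complements are degenerate and rejected.  Degenerate variances: both
    zero with equal means gives (0, 1); both zero with different means gives
    (+/-inf, 0).
    """
    n1 = len(cluster_scores)
    n_all = len(all_scores)
    n2 = n_all - n1
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"degenerate sizes for Q-score: cluster {n1}, complement {n2}"
        )
    cs = np.asarray(cluster_scores, dtype=float)
    asum = float(np.sum(all_scores))
    asq = float(np.sum(np.square(all_scores)))
    s1, sq1 = float(cs.sum()), float(np.square(cs).sum())
    m1 = s1 / n1
    m2 = (asum - s1) / n2
    v1 = max(0.0, (sq1 - n1 * m1 * m1) / (n1 - 1))
    v2 = max(0.0, ((asq - sq1) - n2 * m2 * m2) / (n2 - 1)) if n2 > 1 else 0.0
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        return math.copysign(math.inf, m1 - m2), 0.0
    t = (m1 - m2) / math.sqrt(se2)
    # Welch-Satterthwaite df; a zero-variance group drops out of the sum
    denom = 0.0
    if v1 > 0:
        denom += (v1 / n1) ** 2 / (n1 - 1)
    if v2 > 0 and n2 > 1:
        denom += (v2 / n2) ** 2 / (n2 - 1)
    df = se2**2 / denom if denom > 0 else float(n1 + n2 - 2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, min(1.0, p)


def q_score_one_sample(
    cluster_scores: Sequence[float], all_scores: Sequence[float]
) -> tuple[float, float]:
    """One-sample t of the cluster mean against the overall mean (alternative
    Q-score convention, selectable instead of the Welch two-sample form)."""
    n1 = len(cluster_scores)
    if n1 < 2 or len(all_scores) < 3 or n1 >= len(all_scores):
        raise ValueError("degenerate sizes for Q-score")
    mu = float(np.mean(all_scores))
    cs = np.asarray(cluster_scores, dtype=float)
    v = float(cs.var(ddof=1))
    if v == 0.0:
        if float(cs.mean()) == mu:
            return 0.0, 1.0
        return math.copysign(math.inf, float(cs.mean()) - mu), 0.0
    t = (float(cs.mean()) - mu) / math.sqrt(v / n1)
    p = 2.0 * float(stats.t.sf(abs(t), n1 - 1))
    return t, min(1.0, p)


_QSCORES = {"welch": q_score, "one-sample": q_score_one_sample}


# ---------------------------------------------------------------------------
# genome scan


def _best_cluster(
    clusters: list[list[int]], scores: np.ndarray, qscore: str
) -> tuple[tuple[int, ...], float, float] | None:
    """Max-|Q| cluster among the testable ones (>= 2 members, strict subset).

    Ties: larger |Q|, then smaller p, then larger cluster, then
    lexicographically smallest member tuple.
    """
    qfun = _QSCORES[qscore]
    best = None
    n = len(scores)
    for mem in clusters:
        if len(mem) < 2 or len(mem) > n - 2:
            continue  # need >= 2 members on both sides of the split
        q, p = qfun(scores[mem], scores)
        key = (-abs(q), p, -len(mem), tuple(mem))
        if best is None or key < best[0]:
            best = (key, (tuple(mem), q, p))
    return None if best is None else best[1]


def scan(
    pooled_scores: Sequence[ScoredFounderHaplotype],
    params: SimilarityParams | None = None,
    density: DensityParams | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    permutations: int = 1000,
    qscore: str = "one-sample",
    rng: np.random.Generator | int | None = None,
) -> ScanResult:
    """Marker-by-marker cluster association scan of pooled founder haplotypes.

    ``correction`` is ``bonferroni`` (p_raw times the marker count) or
    ``permutation`` (family-wise p against the permutation null of the
    genome-wide max |Q|, scores shuffled against haplotypes).

    ``qscore`` selects the cluster statistic: ``one-sample`` (default)
    refers the cluster mean to the overall sample mean, which is
    conservative for clusters covering most of the sample; ``welch``
    contrasts cluster against complement and is anti-conservative when the
    complement is a handful of haplotypes.
    """
    if correction not in ("bonferroni", "permutation"):
        raise ValueError(f"unknown correction {correction!r}")
    params = params or SimilarityParams()
    density = density or DensityParams()
    haps = np.asarray([s.haplotype for s in pooled_scores], dtype=np.int64)
    scores = np.asarray([s.score for s in pooled_scores], dtype=float)
    n, n_markers = haps.shape
    if params.window > n_markers:
        warnings.warn(
            f"window {params.window} exceeds the {n_markers}-marker map; clipping",
            stacklevel=2,
        )
    # clustering depends on haplotypes only, so compute it once per marker
    per_marker_clusters: list[list[list[int]]] = []
    for focal in range(n_markers):
        s = _pairwise_similarity(haps, focal, params)
        s_max = max_similarity(focal, n_markers, params)
        per_marker_clusters.append(_cluster_from_similarity(s, s_max, density))

    observed = [
        _best_cluster(per_marker_clusters[f], scores, qscore) for f in range(n_markers)
    ]

    best: list[ClusterResult | None] = []
    if correction == "bonferroni":
        for f, ob in enumerate(observed):
            if ob is None:
                best.append(None)
                continue
            mem, q, p = ob
            best.append(ClusterResult(f, mem, q, p, min(1.0, p * n_markers)))
    else:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        null_max = np.empty(permutations)
        for b in range(permutations):
            perm = gen.permutation(scores)
            qmax = 0.0
            for f in range(n_markers):
                ob = _best_cluster(per_marker_clusters[f], perm, qscore)
                if ob is not None:
                    qmax = max(qmax, abs(ob[1]))
            null_max[b] = qmax
        for f, ob in enumerate(observed):
            if ob is None:
                best.append(None)
                continue
            mem, q, p = ob
            p_adj = (1.0 + float(np.sum(null_max >= abs(q)))) / (permutations + 1.0)
            best.append(ClusterResult(f, mem, q, p, max(p, min(1.0, p_adj))))
    return ScanResult(alpha=alpha, correction=correction, best=best)
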