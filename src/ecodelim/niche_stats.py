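"""Niche overlap, breadth, equivalency and similarity statistics.

Overlap between two lineages is Schoener's D = 1 - 0.5 * sum|p1 - p2|
over their normalized occupancy grids (0 = disjoint niches, 1 =
identical).  Breadth is Levins' inverse concentration B = 1 / sum(p^2),
the effective number of occupied environment-space cells.

Two randomization tests accompany the overlap value:

* the *equivalency* test pools both occurrence sets and repeatedly
  repartitions them into pseudo-groups of the original sizes; niches are
  declared non-equivalent when the observed D falls significantly below
  the null distribution of repartitioned D values (lower one-tailed);
* the *similarity* test asks, directionally, whether one lineage's niche
  sits closer to (or farther from) the other's than a niche of the same
  shape placed at random within the available environment; the null
  relocates the observed occurrence cloud to centroids drawn uniformly
  from the background envelope, preserving its shape.

p-values use the add-one convention p = (1 + hits) / (reps + 1) so a
randomization p is never 0; with 100 replicates the smallest attainable
p is 1/101.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_space import (
    EnvSpaceGrid,
    PcaModel,
    _kde_on_grid,
    build_grid,
    grid_axes,
    project,
    silverman_bandwidth,
)

DEFAULT_ALPHA = 0.05


@dataclass
class BreadthResult:
    lineage: str
    B: float
    B_norm: float


@dataclass
class NicheComparisonResult:
    pair: tuple[str, str]
    D: float
    equivalency_p: float
    similarity_p_ab: float
    similarity_p_ba: float
    verdict_equivalency: str
    verdict_similarity_ab: str
    verdict_similarity_ba: str
    null_equivalency: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    null_similarity_ab: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    null_similarity_ba: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def schoener_D(p1: np.ndarray, p2: np.ndarray) -> float:
    """Schoener's D overlap between two normalized occupancy grids."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"grid shapes differ: {p1.shape} vs {p2.shape}")
    for i, p in enumerate((p1, p2), start=1):
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"grid {i} is not normalized (sums to {p.sum():.8f})")
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def levins_breadth(p: np.ndarray, lineage: str = "") -> BreadthResult:
    """Levins' inverse concentration B = 1 / sum(p^2), with normalized form."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("occupancy grid is all zero")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"grid is not normalized (sums to {total:.8f})")
    B = float(1.0 / np.square(p).sum())
    n = p.size
    B_norm = float((B - 1.0) / (n - 1.0)) if n > 1 else 0.0
    return BreadthResult(lineage=lineage, B=B, B_norm=B_norm)


def _pair_rng(seed, *labels) -> np.random.Generator:
    """Generator whose stream depends on the seed and pair labels only,
    not on lineage input order."""
    tag = zlib.crc32("|".join(str(x) for x in labels).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _shared_grid_builder(background_scores, R, mode):
    """Grid builder with axes and bandwidth frozen on the background.

    Replicate grids in the randomization tests reuse the background
    calibration; only the occurrence points change.
    """
    axes = grid_axes(background_scores, R)
    bw = (
        silverman_bandwidth(background_scores[:, 0]),
        silverman_bandwidth(background_scores[:, 1]),
    )
    xc = 0.5 * (axes[0][:-1] + axes[0][1:])
    yc = 0.5 * (axes[1][:-1] + axes[1][1:])
    e = _kde_on_grid(background_scores, xc, yc, *bw)

    def builder(scores: np.ndarray) -> EnvSpaceGrid:
        return build_grid(scores, background_scores, R=R, mode=mode, bandwidth=bw,
                          axes=axes, precomputed_e=e)

    return builder


@dataclass
class EquivalencyResult:
    D: float
    p: float
    verdict: str
    null: np.ndarray = field(repr=False)


def equivalency_test(
    occ_a: np.ndarray,
    occ_b: np.ndarray,
    background: np.ndarray,
    model: PcaModel | None = None,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    R: int = 100,
    mode: str = "uncorrected",
    alpha: float = DEFAULT_ALPHA,
    exhaustive: bool = False,
    grid_builder=None,
) -> EquivalencyResult:
    """Niche equivalency randomization test (lower one-tailed).

    ``occ_a``, ``occ_b`` and ``background`` are environmental vectors if
    ``model`` is given (they are projected onto its first two axes), or
    already 2-D ordination scores if ``model`` is None.  ``grid_builder``
    may replace the kernel-grid construction (scores -> object with a
    normalized ``p`` attribute or a bare normalized array); it exists so
    the permutation machinery can be exercised on analytically tractable
    spaces.  ``exhaustive=True`` enumerates every partition of the pooled
    points into groups of the original sizes instead of sampling ``reps``
    random repartitions.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model is not None:
        occ_a = project(occ_a, model)
        occ_b = project(occ_b, model)
        background = project(background, model)
    occ_a = np.atleast_2d(np.asarray(occ_a, dtype=float))
    occ_b = np.atleast_2d(np.asarray(occ_b, dtype=float))
    if grid_builder is None and min(len(occ_a), len(occ_b)) < 5 and not exhaustive:
        raise ValueError("each lineage needs >= 5 occurrences")
    if grid_builder is None:
        grid_builder = _shared_grid_builder(np.asarray(background, dtype=float), R, mode)

    def p_of(scores):
        g = grid_builder(scores)
        return g.p if hasattr(g, "p") else np.asarray(g, dtype=float)

    D_obs = schoener_D(p_of(occ_a), p_of(occ_b))
    pooled = np.vstack([occ_a, occ_b])
    n_a, n_tot = len(occ_a), len(pooled)

    if exhaustive:
        null = np.array([
            schoener_D(p_of(pooled[list(idx)]),
                       p_of(pooled[[i for i in range(n_tot) if i not in set(idx)]]))
            for idx in itertools.combinations(range(n_tot), n_a)
        ])
        pval = float((null <= D_obs + 1e-12).sum() / null.size)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = np.empty(reps)
        for r in range(reps):
            perm = rng.permutation(n_tot)
            null[r] = schoener_D(p_of(pooled[perm[:n_a]]), p_of(pooled[perm[n_a:]]))
        pval = float((1 + (null <= D_obs + 1e-12).sum()) / (reps + 1))
    verdict = "Different" if pval < alpha else "Equivalent (not rejected)"
    return EquivalencyResult(D=D_obs, p=pval, verdict=verdict, null=null)


@dataclass
class SimilarityResult:
    D: float
    p_similar: float
    p_different: float
    verdict: str
    null: np.ndarray = field(repr=False)


def similarity_test(
    grid_a: EnvSpaceGrid,
    occ_b: np.ndarray,
    background_b: np.ndarray,
    model: PcaModel | None = None,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    R: int = 100,
    mode: str = "uncorrected",
    alpha: float = DEFAULT_ALPHA,
    resample_points: bool = False,
) -> SimilarityResult:
    """Directional niche similarity test of lineage b against grid_a.

    The null preserves the shape of b's occurrence cloud and relocates
    its centroid uniformly within b's background envelope (clipping to
    the grid bounds), then recomputes D against a's observed grid.  With
    ``resample_points=True`` the null instead draws ``len(occ_b)`` points
    uniformly from the envelope (a cruder, shape-destroying variant).

    Two one-sided p's are returned: p_similar (observed overlap at or
    above the null) and p_different (at or below).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model is not None:
        occ_b = project(occ_b, model)
        background_b = project(background_b, model)
    occ_b = np.atleast_2d(np.asarray(occ_b, dtype=float))
    background_b = np.atleast_2d(np.asarray(background_b, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # b's grids share a's axes so the D comparison is cell-by-cell
    axes = (grid_a.x_edges, grid_a.y_edges)
    bw = grid_a.bandwidth
    xc = 0.5 * (axes[0][:-1] + axes[0][1:])
    yc = 0.5 * (axes[1][:-1] + axes[1][1:])
    e_b = _kde_on_grid(background_b, xc, yc, *bw)

    def b_grid(scores):
        return build_grid(scores, background_b, R=grid_a.resolution, mode=mode,
                          bandwidth=bw, axes=axes, precomputed_e=e_b)

    D_obs = schoener_D(grid_a.p, b_grid(occ_b).p)
    lo = background_b.min(axis=0)
    hi = background_b.max(axis=0)
    centroid = occ_b.mean(axis=0)
    null = np.empty(reps)
    for r in range(reps):
        if resample_points:
            shifted = rng.uniform(lo, hi, size=occ_b.shape)
        else:
            target = rng.uniform(lo, hi)
            shifted = occ_b + (target - centroid)
            shifted = np.clip(shifted, lo, hi)
        null[r] = schoener_D(grid_a.p, b_grid(shifted).p)
    p_similar = float((1 + (null >= D_obs - 1e-12).sum()) / (reps + 1))
    p_different = float((1 + (null <= D_obs + 1e-12).sum()) / (reps + 1))
    if p_similar < alpha:
        verdict = "Similar"
    elif p_different < alpha:
        verdict = "Different"
    else:
        verdict = "ns"
    return SimilarityResult(D=D_obs, p_similar=p_similar, p_different=p_different,
                            verdict=verdict, null=null)


def compare_all(
    lineage_occurrences: dict[str, np.ndarray],
    background: np.ndarray,
    model: PcaModel | None = None,
    reps: int = 100,
    seed: int = 0,
    R: int = 100,
    mode: str = "uncorrected",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """All pairwise niche comparisons plus per-lineage breadth.

    Returns (comparisons table, breadth table, detail dict keyed by pair
    and lineage).  One row per unordered lineage pair: D, directional
    similarity p's, equivalency p, and the verdicts at the given alpha.
    Per-pair random streams are derived from the seed and the pair
    labels, so results do not depend on lineage input order.
    """
    if len(lineage_occurrences) < 2:
        raise ValueError("need at least 2 lineages")
    if model is not None:
        scores = {k: project(v, model) for k, v in lineage_occurrences.items()}
        bg = project(background, model)
    else:
        scores = {k: np.atleast_2d(np.asarray(v, dtype=float))
                  for k, v in lineage_occurrences.items()}
        bg = np.atleast_2d(np.asarray(background, dtype=float))

    builder = _shared_grid_builder(bg, R, mode)
    names = sorted(scores)
    grids = {k: builder(scores[k]) for k in names}

    breadth_rows = []
    for k in names:
        b = levins_breadth(grids[k].p, lineage=k)
        breadth_rows.append({"lineage": k, "B": b.B, "B_norm": b.B_norm})

    detail: dict = {"grids": grids}
    rows = []
    for a, b in itertools.combinations(names, 2):
        eq = equivalency_test(
            scores[a], scores[b], bg, reps=reps, seed=_pair_rng(seed, "eq", a, b),
            R=R, mode=mode, alpha=alpha, grid_builder=builder,
        )
        sim_ab = similarity_test(
            grids[a], scores[b], bg, reps=reps, seed=_pair_rng(seed, "sim", a, b),
            R=R, mode=mode, alpha=alpha,
        )
        sim_ba = similarity_test(
            grids[b], scores[a], bg, reps=reps, seed=_pair_rng(seed, "sim", b, a),
            R=R, mode=mode, alpha=alpha,
        )
        res = NicheComparisonResult(
            pair=(a, b),
            D=eq.D,
            equivalency_p=eq.p,
            similarity_p_ab=sim_ab.p_similar,
            similarity_p_ba=sim_ba.p_similar,
            verdict_equivalency=eq.verdict,
            verdict_similarity_ab=sim_ab.verdict,
            verdict_similarity_ba=sim_ba.verdict,
            null_equivalency=eq.null,
            null_similarity_ab=sim_ab.null,
            null_similarity_ba=sim_ba.null,
        )
        detail[(a, b)] = res
        rows.append({
            "lineage_a": a,
            "lineage_b": b,
            "D": res.D,
            "similarity_ab_p": res.similarity_p_ab,
            "similarity_ab_verdict": res.verdict_similarity_ab,
            "similarity_ba_p": res.similarity_p_ba,
            "similarity_ba_verdict": res.verdict_similarity_ba,
            "equivalency_p": res.equivalency_p,
            "equivalency_verdict": res.verdict_equivalency,
        })
    return pd.DataFrame(rows), pd.DataFrame(breadth_rows), detail
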