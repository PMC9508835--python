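"""Differential reactivity detection and structure-model comparison.

Two complementary comparisons live here:

* :func:`delta_shape` - windowed, significance-tested comparison of two
  reactivity profiles.  Differences are smoothed over a centered window
  (default 5 nt), and a site is significant only if it passes both a
  Z-factor test (separation of the smoothed means beyond their combined
  standard errors) and a standard-score test (|Z| >= 1 against the
  distribution of smoothed differences), with at least 3 passing
  positions inside the window.
* :func:`sens_ppv` / :func:`overall_similarity` - base-pair level
  agreement between structure models: sensitivity (fraction of reference
  pairs recovered), positive predictive value (fraction of model pairs
  that are in the reference), and their arithmetic mean ("overall
  similarity"), computed from pairing-probability matrices thresholded at
  0.1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .fold import PairProbabilityMatrix
from .reactivity import ReactivityProfile

__all__ = [
    "DeltaShapeResult",
    "SimilarityScore",
    "delta_shape",
    "sens_ppv",
    "probability_pair_set",
    "overall_similarity",
]

DEFAULT_CUTOFF = 0.1
ZF_CONFIDENCE = 1.96


@dataclass
class DeltaShapeResult:
    """Per-position statistics from a profile comparison (1-based arrays)."""

    diff: np.ndarray          # smoothed mean difference, a - b
    z_factor: np.ndarray
    std_score: np.ndarray
    significant: np.ndarray   # bool
    direction: np.ndarray     # "increase" / "decrease" / ""

    def significant_positions(self) -> list[int]:
        return [int(i) + 1 for i in np.nonzero(self.significant)[0]]


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean ignoring NaNs; NaN where the window is empty."""
    n = len(values)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        chunk = values[max(0, i - half):min(n, i + half + 1)]
        good = chunk[~np.isnan(chunk)]
        if good.size:
            out[i] = good.mean()
    return out


def delta_shape(
    profile_a: ReactivityProfile,
    profile_b: ReactivityProfile,
    window: int = 5,
    exclusions: Sequence[tuple[int, int]] = (),
    min_hits: int = 3,
) -> DeltaShapeResult:
    """Detect significant reactivity differences between two profiles.

    ``exclusions`` are closed 1-based intervals (e.g. primer-binding
    regions) that can never be called significant.  Swapping the two
    profiles flips every direction but leaves the significant set intact.
    """
    if len(profile_a) != len(profile_b):
        raise ValueError(
            f"profile lengths differ: {len(profile_a)} vs {len(profile_b)}"
        )
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = len(profile_a)
    excluded = np.zeros(n, dtype=bool)
    for start, end in exclusions:
        excluded[max(0, start - 1):min(n, end)] = True

    va, vb = profile_a.values.copy(), profile_b.values.copy()
    ea = np.where(np.isnan(profile_a.stderr), 0.0, profile_a.stderr)
    eb = np.where(np.isnan(profile_b.stderr), 0.0, profile_b.stderr)
    va[excluded] = np.nan
    vb[excluded] = np.nan

    mu_a, mu_b = _smooth(va, window), _smooth(vb, window)
    se_a = _smooth(np.where(np.isnan(va), np.nan, ea), window)
    se_b = _smooth(np.where(np.isnan(vb), np.nan, eb), window)
    diff = mu_a - mu_b

    with np.errstate(divide="ignore", invalid="ignore"):
        z_factor = 1.0 - ZF_CONFIDENCE * (se_a + se_b) / np.abs(diff)
    ok = ~np.isnan(diff)
    if ok.sum() >= 2 and np.nanstd(diff[ok]) > 0:
        std_score = (diff - np.nanmean(diff[ok])) / np.nanstd(diff[ok])
    else:
        std_score = np.zeros(n)

    prelim = ok & ~np.isnan(z_factor) & (z_factor > 0) & (np.abs(std_score) >= 1)
    prelim &= ~excluded

    half = window // 2
    significant = np.zeros(n, dtype=bool)
    for i in np.nonzero(prelim)[0]:
        hits = prelim[max(0, i - half):min(n, i + half + 1)].sum()
        if hits >= min_hits:
            significant[i] = True

    direction = np.array([""] * n, dtype=object)
    direction[significant & (diff > 0)] = "increase"
    direction[significant & (diff < 0)] = "decrease"
    return DeltaShapeResult(
        diff=diff, z_factor=z_factor, std_score=std_score,
        significant=significant, direction=direction,
    )


@dataclass
class SimilarityScore:
    sens: float
    ppv: float
    cutoff: float = DEFAULT_CUTOFF

    @property
    def overall(self) -> float:
        return 0.5 * (self.sens + self.ppv)


def sens_ppv(model: Iterable[tuple[int, int]],
             reference: Iterable[tuple[int, int]],
             cutoff: float = DEFAULT_CUTOFF) -> SimilarityScore:
    """Base-pair sensitivity and PPV of ``model`` against ``reference``.

    Empty-set convention: an empty reference gives sens = 1 only if the
    model is also empty (otherwise 0), and symmetrically for PPV.
    """
    m = {tuple(sorted(p)) for p in model}
    r = {tuple(sorted(p)) for p in reference}
    shared = len(m & r)
    if r:
        sens = shared / len(r)
    else:
        sens = 1.0 if not m else 0.0
    if m:
        ppv = shared / len(m)
    else:
        ppv = 1.0 if not r else 0.0
    return SimilarityScore(sens=sens, ppv=ppv, cutoff=cutoff)


def probability_pair_set(matrix: PairProbabilityMatrix,
                         cutoff: float = DEFAULT_CUTOFF) -> frozenset:
    """Pairs (i, j), i < j, with probability >= cutoff (inclusive)."""
    iu, ju = np.triu_indices(matrix.n, k=1)
    keep = matrix.p[iu, ju] >= cutoff
    return frozenset(zip((iu[keep] + 1).tolist(), (ju[keep] + 1).tolist()))


def _restrict(pairs: frozenset, region: Optional[tuple[int, int]]) -> frozenset:
    if region is None:
        return pairs
    lo, hi = region
    if hi < lo:
        raise ValueError(f"empty region ({lo}, {hi})")
    return frozenset((i, j) for i, j in pairs if lo <= i <= hi and lo <= j <= hi)


def overall_similarity(
    matrix_a: PairProbabilityMatrix,
    matrix_b: PairProbabilityMatrix,
    region: Optional[tuple[int, int]] = None,
    cutoff: float = DEFAULT_CUTOFF,
    symmetric: bool = False,
) -> float:
    """Overall similarity of two pairing-probability matrices.

    Both matrices are thresholded at ``cutoff``, restricted to pairs with
    both ends inside ``region`` (closed, 1-based), and compared with
    ``matrix_b`` as the reference.  With ``symmetric=True`` the mean over
    both orientations is returned instead.
    """
    if matrix_a.n != matrix_b.n:
        raise ValueError("matrices have different dimensions")
    set_a = _restrict(probability_pair_set(matrix_a, cutoff), region)
    set_b = _restrict(probability_pair_set(matrix_b, cutoff), region)
    forward = sens_ppv(set_a, set_b, cutoff).overall
    if not symmetric:
        return forward
    backward = sens_ppv(set_b, set_a, cutoff).overall
    return 0.5 * (forward + backward)
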