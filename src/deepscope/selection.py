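"""Haplotype-segment machinery and selection scores.

Implements the haplotype estimated breeding value (HEBV) over sliding marker
windows, the H-score (novel favorable haplotypes relative to an elite set),
the masked two-genotype variance S-score, the usefulness criterion and the
selection-intensity constant.

Segments are windows of ``window`` consecutive markers per chromosome whose
starts are ``step`` markers apart; the HEBV of a pair of individuals is

    HEBV(i, j) = lambda * sum_h max(H[2i,h], H[2i+1,h], H[2j,h], H[2j+1,h])

with H the per-haplotype segment-value matrix and lambda = step / window the
de-duplication factor for overlapping windows.  With step = window (lambda =
1) the HEBV of an individual with itself reduces to the optimal haploid value
(OHV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import GenomeLayout
from .meiosis import single_seed_descent, cross_batch

__all__ = [
    "SegmentMap",
    "build_segments",
    "HebvMatrix",
    "hebv_matrix",
    "pairwise_hebv",
    "h_score",
    "h_scores",
    "s_score",
    "PVector",
    "usefulness",
    "selection_intensity",
    "predict_progeny_mean_sd",
]


@dataclass(frozen=True)
class SegmentMap:
    """Haplotype-segment windows over the marker columns.

    ``segments`` is a list of (start, stop) half-open index ranges into the
    marker-column order (markers sorted by global locus index, hence
    contiguous per chromosome).  ``lam`` is the global step/window ratio,
    kept even for a truncated final window.
    """

    window: int
    step: int
    segments: list[tuple[int, int]]
    segment_chrom: np.ndarray
    n_markers: int

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lam(self) -> float:
        return self.step / self.window

    def membership_matrix(self) -> np.ndarray:
        """Dense k x n_H indicator M with M[i, j] = 1 iff marker i is in segment j."""
        M = np.zeros((self.n_markers, self.n_segments), dtype=np.int8)
        for j, (a, b) in enumerate(self.segments):
            M[a:b, j] = 1
        return M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (j + 1, int(self.segment_chrom[j]) + 1, a + 1, b)
                for j, (a, b) in enumerate(self.segments)
            ],
            columns=["segment", "chromosome", "first_marker", "last_marker"],
        )


def _chromosome_starts(m: int, window: int, step: int) -> list[int]:
    if m <= window:
        return [0]
    starts = list(range(0, m - window + 1, step))
    if starts[-1] != m - window:  # end-anchored final window keeps all markers
        starts.append(m - window)
    return starts


def build_segments(
    layout: GenomeLayout, window: int = 20, step: int = 5
) -> SegmentMap:
    """Divide each chromosome's markers into sliding windows.

    Windows start at marker 0, step, 2*step, ... within the chromosome; if
    leftover markers remain a final window is anchored at the chromosome end.
    Chromosomes shorter than ``window`` yield one full-chromosome segment.
    Windows never span chromosomes.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    counts = [
        int(np.sum(layout.chrom_of[layout.marker_indices] == c))
        for c in range(layout.n_chromosomes)
    ]
    return segments_from_counts(counts, window, step)


def segments_from_counts(
    markers_per_chromosome: list[int], window: int = 20, step: int = 5
) -> SegmentMap:
    """Build a SegmentMap from explicit per-chromosome marker counts."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    segments: list[tuple[int, int]] = []
    chrom: list[int] = []
    offset = 0
    for c, m in enumerate(markers_per_chromosome):
        if m == 0:
            continue
        w = min(window, m)
        for s in _chromosome_starts(m, window, step):
            segments.append((offset + s, offset + s + w))
            chrom.append(c)
        offset += m
    return SegmentMap(
        window=window,
        step=step,
        segments=segments,
        segment_chrom=np.array(chrom, dtype=int),
        n_markers=offset,
    )


@dataclass
class HebvMatrix:
    """Per-haplotype segment values; rows 2i and 2i+1 belong to individual i."""

    values: np.ndarray  # (2n, n_segments)
    lam: float

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0] // 2

    def segment_max(self) -> np.ndarray:
        """Per-individual best haplotype value per segment, shape (n, n_H)."""
        v = self.values
        return np.maximum(v[0::2], v[1::2])


def hebv_matrix(
    X: np.ndarray, effects: np.ndarray, segmap: SegmentMap
) -> HebvMatrix:
    """H = (X o 1 beta') M : per-haplotype sums of carried marker effects.

    ``X`` is the (2n, k) 0/1 haplotype matrix over the marker columns and
    ``effects`` the k estimated marker effects.  Computed with a column
    cumulative sum since segments are contiguous runs of marker columns.
    """
    X = np.asarray(X, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if X.ndim != 2 or X.shape[1] != segmap.n_markers or effects.size != segmap.n_markers:
        raise ValueError("haplotype matrix / effects do not match the segment map")
    weighted = X * effects[None, :]
    csum = np.concatenate(
        [np.zeros((X.shape[0], 1)), np.cumsum(weighted, axis=1)], axis=1
    )
    H = np.empty((X.shape[0], segmap.n_segments))
    for j, (a, b) in enumerate(segmap.segments):
        H[:, j] = csum[:, b] - csum[:, a]
    return HebvMatrix(values=H, lam=segmap.lam)


def pairwise_hebv(i: int, j: int, hebv: HebvMatrix, lam: float | None = None) -> float:
    """HEBV between individuals i and j (i = j gives the single-individual
    value; at lambda = 1 with non-overlapping windows that is the OHV)."""
    lam = hebv.lam if lam is None else lam
    v = hebv.values
    four = np.stack([v[2 * i], v[2 * i + 1], v[2 * j], v[2 * j + 1]])
    return float(lam * four.max(axis=0).sum())


def h_scores(
    candidate_segmax: np.ndarray, elite_segmax: np.ndarray, lam: float
) -> np.ndarray:
    """H-score of each candidate: max over elites of the pairwise HEBV.

    Both arguments are per-individual segment maxima (rows: individuals,
    columns: segments).  Vectorized over all candidate x elite pairs.
    """
    if elite_segmax.shape[0] == 0:
        raise ValueError("elite set must be nonempty")
    pair = np.maximum(candidate_segmax[:, None, :], elite_segmax[None, :, :]).sum(axis=2)
    return lam * pair.max(axis=1)


def h_score(
    candidate: int, elite_ids: np.ndarray, hebv: HebvMatrix, lam: float | None = None
) -> float:
    """H(i) = max_{j in E} HEBV(i, j) for one candidate index."""
    elite_ids = np.asarray(elite_ids, dtype=int)
    if elite_ids.size == 0:
        raise ValueError("elite set must be nonempty")
    lam = hebv.lam if lam is None else lam
    return max(pairwise_hebv(candidate, j, hebv, lam) for j in elite_ids)


def s_score(
    zi: np.ndarray, zj: np.ndarray, p: np.ndarray, divisor: float = 2.0
) -> float:
    """Masked two-genotype variance sum S(i,j) = sum_m var{Z_im, Z_jm} p_m.

    The two-point variance uses the n-1 denominator, var{a,b} = (a-b)^2/2;
    ``divisor=4.0`` switches to the n-denominator convention.  The choice
    rescales every score by a constant and cannot change any argmax.
    """
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (zi.size == zj.size == p.size):
        raise ValueError("genotypes and mask must have equal length")
    return float((((zi - zj) ** 2) / divisor * p).sum())


def s_scores(
    zi: np.ndarray, Z_candidates: np.ndarray, p: np.ndarray, divisor: float = 2.0
) -> np.ndarray:
    """S-score of one genotype against each row of a candidate matrix."""
    d = (np.asarray(Z_candidates, dtype=float) - np.asarray(zi, dtype=float)[None, :]) ** 2
    return (d / divisor) @ np.asarray(p, dtype=float)


class PVector:
    """Per-marker mask: 1 while not both alleles are secured in the current
    parental set, 0 once they are.  Monotone non-increasing within a cycle."""

    def __init__(self, n_markers: int) -> None:
        self._seen0 = np.zeros(n_markers, dtype=bool)
        self._seen1 = np.zeros(n_markers, dtype=bool)

    @property
    def values(self) -> np.ndarray:
        return (~(self._seen0 & self._seen1)).astype(np.int8)

    def update(self, genotype: np.ndarray) -> "PVector":
        """Register a committed parent (genotype coded -1/0/1)."""
        z = np.asarray(genotype)
        self._seen0 |= z <= 0
        self._seen1 |= z >= 0
        return self

    def reset(self) -> None:
        self._seen0[:] = False
        self._seen1[:] = False


def usefulness(mu_hat: float, sigma_hat: float, i: float = 2.06, rho: float = 1.0) -> float:
    """Usefulness criterion U = mu_hat + i * rho * sigma_hat."""
    if sigma_hat < 0:
        raise ValueError("progeny standard deviation must be nonnegative")
    return mu_hat + i * rho * sigma_hat


def selection_intensity(fraction: float) -> float:
    """Mean of a standard normal truncated to its upper ``fraction`` tail.

    At fraction 0.05 this is phi(z_{0.95}) / 0.05 ~= 2.06, the constant used
    in the usefulness criterion.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    z = norm.ppf(1 - fraction)
    return float(norm.pdf(z) / fraction)


def predict_progeny_mean_sd(
    p1_haplotypes: np.ndarray,
    p2_haplotypes: np.ndarray,
    u: np.ndarray,
    layout: GenomeLayout,
    n_virtual_progeny: int = 200,
    rng: np.random.Generator | None = None,
    ssd_generations: int = 2,
) -> tuple[float, float]:
    """Monte-Carlo progeny mean and SD of GEBVs for one candidate cross.

    Simulates ``n_virtual_progeny`` in-silico F3 offspring (meiosis plus two
    single-seed-descent generations by default) and scores them with the
    estimated marker effects ``u``.  Replaces the analytic progeny-covariance
    construction with a simulation of the very process it approximates.
    """
    rng = np.random.default_rng(rng)
    h1 = np.repeat(np.asarray(p1_haplotypes)[None], n_virtual_progeny, axis=0)
    h2 = np.repeat(np.asarray(p2_haplotypes)[None], n_virtual_progeny, axis=0)
    f1 = cross_batch(h1, h2, layout, rng)
    f3 = single_seed_descent(f1, ssd_generations, layout, rng)
    Z = f3[:, :, layout.marker_indices].sum(axis=1) - 1.0
    g = Z @ np.asarray(u, dtype=float)
    return float(g.mean()), float(g.std(ddof=1))
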