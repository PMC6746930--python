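"""Windowed gene-retention profiles and informative-window flags.

A retention profile holds, for every reference chromosome, the fraction of
reference genes in each window of ``M`` consecutive gene ranks that still
have a collinear copy in each subgenome track. Windows with nearly equal
retention across tracks carry no directional signal about biased
fractionation; the flag computation marks them uninformative using the
relative difference

    d_i = |A_i - B_i| / (0.5 (A_i + B_i)),

with a window informative (delta_i = 1) iff d_i >= tau (default 0.05).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RetentionProfile",
    "WindowFlags",
    "compute_retention",
    "compute_flags",
    "profile_from_masks",
]


@dataclass
class RetentionProfile:
    """Per-chromosome windowed retention rates for S subgenome tracks.

    Attributes
    ----------
    rates : chrom -> (S, N_c) array of retention rates in [0, 1].
    window_gene_counts : chrom -> (N_c,) int array; the trailing window may
        hold fewer than M genes.
    M : window size in reference genes.
    """

    rates: dict[str, np.ndarray]
    window_gene_counts: dict[str, np.ndarray]
    M: int

    def __post_init__(self):
        for chrom, A in self.rates.items():
            if A.ndim != 2:
                raise ValueError(f"{chrom}: rates must be (S, N_c)")
            if np.any(A < 0) or np.any(A > 1):
                raise ValueError(f"{chrom}: retention rates outside [0, 1]")
            if A.shape[1] != len(self.window_gene_counts[chrom]):
                raise ValueError(f"{chrom}: window count mismatch")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.rates)

    @property
    def S(self) -> int:
        first = next(iter(self.rates.values()))
        return first.shape[0]

    @property
    def K(self) -> int:
        return len(self.rates)

    def n_windows(self, chrom: str) -> int:
        return self.rates[chrom].shape[1]

    def subset_tracks(self, tracks: tuple[int, ...]) -> "RetentionProfile":
        """A new profile restricted to the given track indices, in order."""
        idx = list(tracks)
        return RetentionProfile(
            rates={c: A[idx, :] for c, A in self.rates.items()},
            window_gene_counts={
                c: n.copy() for c, n in self.window_gene_counts.items()
            },
            M=self.M,
        )


@dataclass
class WindowFlags:
    """Informative-window flags per chromosome.

    ``d`` holds the (signed-free) relative retention difference per window,
    ``delta`` the {0,1} indicator d >= tau. ``delta_count(c)`` is the number
    of *uninformative* windows on chromosome c.
    """

    d: dict[str, np.ndarray]
    delta: dict[str, np.ndarray]
    tau: float
    pair_set: tuple[tuple[int, int], ...] = ((0, 1),)
    pair_norm: str = "pairs"

    def delta_count(self, chrom: str) -> int:
        return int(len(self.delta[chrom]) - self.delta[chrom].sum())

    def n_informative(self, chrom: str) -> int:
        return int(self.delta[chrom].sum())


def _relative_difference(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|A-B| / (0.5 (A+B)), defined as 0 where both rates are 0."""
    denom = 0.5 * (A + B)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(A - B) / denom
    return np.where(denom > 0, d, 0.0)


def compute_retention(
    assignment,
    M: int = 100,
    min_last_window: float = 0.5,
) -> RetentionProfile:
    """Window a subgenome assignment into per-track retention rates.

    Windows are consecutive, non-overlapping runs of ``M`` reference gene
    ranks (half-open). The trailing partial window is kept iff it holds at
    least ``min_last_window * M`` genes; chromosomes shorter than that are
    excluded with a warning. Rates divide by the actual gene count of the
    window.
    """
    if M < 10:
        raise ValueError(f"window size M={M} too small (need >= 10)")
    rates: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    min_genes = min_last_window * M
    for chrom in assignment.chromosomes:
        n = assignment.n_genes[chrom]
        if n < min_genes:
            logger.warning(
                "chromosome %s has %d genes (< %.0f); excluded", chrom, n, min_genes
            )
            continue
        edges = list(range(0, n + 1, M))
        if edges[-1] != n:
            if n - edges[-1] >= min_genes:
                edges.append(n)
            # else: drop the short tail
        n_win = len(edges) - 1
        S = assignment.S
        A = np.zeros((S, n_win))
        wcounts = np.diff(edges).astype(int)
        tracks = assignment.tracks[chrom]
        for k in range(S):
            retained_ranks = np.fromiter(tracks[k].keys(), dtype=int, count=len(tracks[k]))
            retained_ranks = retained_ranks[retained_ranks < edges[-1]]
            hist, _ = np.histogram(retained_ranks, bins=edges)
            A[k, :] = hist / wcounts
        rates[chrom] = A
        counts[chrom] = wcounts
    if not rates:
        raise ValueError("no chromosome long enough to window")
    return RetentionProfile(rates=rates, window_gene_counts=counts, M=M)


def profile_from_masks(
    masks: dict[str, np.ndarray],
    M: int = 100,
    min_last_window: float = 0.5,
) -> RetentionProfile:
    """Build a profile directly from boolean retention masks.

    ``masks`` maps chromosome -> (S, n_genes) boolean array where True means
    the reference gene at that rank is retained in that subgenome. Used by
    the fractionation simulator, where the full masks are known and no
    collinearity inference is involved.
    """
    if M < 10:
        raise ValueError(f"window size M={M} too small (need >= 10)")
    rates: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    min_genes = min_last_window * M
    for chrom, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        n = mask.shape[1]
        if n < min_genes:
            logger.warning("chromosome %s too short; excluded", chrom)
            continue
        edges = list(range(0, n + 1, M))
        if edges[-1] != n and n - edges[-1] >= min_genes:
            edges.append(n)
        wcounts = np.diff(edges).astype(int)
        n_win = len(wcounts)
        trimmed = mask[:, : edges[-1]].astype(float)
        A = np.add.reduceat(trimmed, edges[:-1], axis=1)[:, :n_win] / wcounts
        rates[chrom] = A
        counts[chrom] = wcounts
    if not rates:
        raise ValueError("no chromosome long enough to window")
    return RetentionProfile(rates=rates, window_gene_counts=counts, M=M)


def compute_flags(
    profile: RetentionProfile,
    tau: float = 0.05,
    pair_set: tuple[tuple[int, int], ...] | None = None,
    pair_norm: str = "pairs",
) -> WindowFlags:
    """Mark windows informative where subgenome retention rates diverge.

    For two tracks, d_i is the single pairwise relative difference. For
    S > 2 it aggregates |pairwise relative differences| over ``pair_set``
    (default: all k < j), divided by the number of pairs (``pair_norm =
    'pairs'``, the form that reduces exactly to the two-track definition) or
    by S (``pair_norm = 'S'``, the literal published variant).
    """
    if not (0 < tau < 1):
        raise ValueError(f"tau={tau} outside (0, 1)")
    S = profile.S
    if pair_set is None:
        pair_set = tuple(itertools.combinations(range(S), 2))
    else:
        pair_set = tuple(tuple(p) for p in pair_set)
    if not pair_set:
        raise ValueError("pair_set is empty")
    for k, j in pair_set:
        if not (0 <= k < S and 0 <= j < S):
            raise ValueError(f"pair ({k}, {j}) invalid for S={S}")
    if pair_norm not in ("pairs", "S"):
        raise ValueError(f"pair_norm={pair_norm!r}; use 'pairs' or 'S'")
    divisor = len(pair_set) if pair_norm == "pairs" else S

    d: dict[str, np.ndarray] = {}
    delta: dict[str, np.ndarray] = {}
    for chrom, A in profile.rates.items():
        acc = np.zeros(A.shape[1])
        for k, j in pair_set:
            acc += _relative_difference(A[k], A[j])
        d_c = acc / divisor
        d[chrom] = d_c
        delta[chrom] = (d_c >= tau).astype(int)
    return WindowFlags(d=d, delta=delta, tau=tau, pair_set=pair_set, pair_norm=pair_norm)
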