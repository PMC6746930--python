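"""Partition collinear blocks into subgenome tracks along reference chromosomes.

A whole-genome duplication leaves S homoeologous copies of every ancestral
region in the polyploid. After chromosome breakage and fractionation these
copies survive as scattered collinear blocks against an outgroup reference.
This module stitches the blocks back into S tracks per reference
chromosome — the reference acts as the scaffold that pitches broken
segments of a chromosome together — and labels the dominant (most-retained)
and sensitive (most-fractionated) tracks.

Tiling is greedy and fully deterministic. The placement unit defaults to
the set of blocks that share a query chromosome (segments of one query
chromosome belong to one subgenome copy and must land on one track);
block-level placement is available via ``group_by_query=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CollinearBlockSet, GenePositionTable

logger = logging.getLogger(__name__)

__all__ = ["SubgenomeAssignment", "partition_subgenomes", "label_dominance"]

LOST = "LOST"


@dataclass
class SubgenomeAssignment:
    """S retained/lost tracks over reference gene ranks, per chromosome.

    ``tracks[chrom][k]`` maps reference rank -> retained query gene id; ranks
    absent from the map are lost in that track. ``dominance_order`` lists
    track indices most-retained first (ties keep input order).
    """

    S: int
    n_genes: dict[str, int]
    tracks: dict[str, list[dict[int, str]]]
    provenance: dict[str, list[list[str]]] = field(default_factory=dict)
    dominance_order: list[int] | None = None

    @property
    def chromosomes(self) -> list[str]:
        return list(self.tracks)

    def retained_counts(self) -> np.ndarray:
        """Total retained genes per track index across chromosomes."""
        counts = np.zeros(self.S, dtype=int)
        for chrom_tracks in self.tracks.values():
            for k, track in enumerate(chrom_tracks):
                counts[k] += len(track)
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Long-format track table: one row per (chrom, rank, track)."""
        rows = []
        for chrom, chrom_tracks in self.tracks.items():
            n = self.n_genes[chrom]
            for k, track in enumerate(chrom_tracks):
                for rank in range(n):
                    rows.append((chrom, rank, k, track.get(rank, LOST)))
        return pd.DataFrame(
            rows, columns=["ref_chrom", "ref_rank", "track", "qry_gene"]
        )

    def write_tracks(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _group_units(blocks, group_by_query: bool):
    """Placement units: lists of blocks, grouped by query chromosome or single."""
    if not group_by_query:
        return [[b] for b in blocks]
    by_qry: dict[str, list] = {}
    for b in blocks:
        by_qry.setdefault(b.qry_chromosome, []).append(b)
    return list(by_qry.values())


def partition_subgenomes(
    blocks: CollinearBlockSet,
    ref: GenePositionTable,
    S: int,
    overlap_frac: float = 0.10,
    group_by_query: bool = True,
) -> SubgenomeAssignment:
    """Greedily tile collinear blocks onto S tracks per reference chromosome.

    Units (query-chromosome groups by default, single blocks otherwise) are
    sorted by total anchor count (desc), then total reference span (desc),
    then query chromosome name, then reference start. Each unit goes on the
    lowest-index track where it collides with already-placed reference ranks
    on fewer than ``overlap_frac`` of its anchor genes; residual colliding
    ranks are trimmed from the newcomer. Units that fit no track are
    discarded with a warning.
    """
    if S < 2:
        raise ValueError(f"S={S}; at least 2 subgenomes required")

    by_ref: dict[str, list] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chromosome, []).append(b)

    tracks: dict[str, list[dict[int, str]]] = {}
    provenance: dict[str, list[list[str]]] = {}
    n_genes: dict[str, int] = {}
    n_discarded = 0

    for chrom in ref.chromosomes:
        chrom_blocks = by_ref.get(chrom)
        if not chrom_blocks:
            logger.warning("reference chromosome %s has no blocks; omitted", chrom)
            continue
        units = _group_units(chrom_blocks, group_by_query)

        def unit_key(unit):
            anchors = sum(b.n_anchors for b in unit)
            span = sum(b.ref_interval[1] - b.ref_interval[0] for b in unit)
            qry = min(b.qry_chromosome for b in unit)
            start = min(b.ref_interval[0] for b in unit)
            return (-anchors, -span, qry, start)

        units.sort(key=unit_key)
        chrom_tracks: list[dict[int, str]] = [dict() for _ in range(S)]
        chrom_prov: list[list[str]] = [[] for _ in range(S)]
        for unit in units:
            placement = {}
            for b in unit:
                for a in b.anchors:
                    placement[ref.rank(a.ref_gene_id)] = a.qry_gene_id
            placed = False
            for k in range(S):
                occupied = chrom_tracks[k].keys()
                colliding = placement.keys() & occupied
                if len(colliding) < overlap_frac * len(placement):
                    for rank in colliding:  # trim residual overlap from newcomer
                        del placement[rank]
                    chrom_tracks[k].update(placement)
                    chrom_prov[k].extend(b.block_id for b in unit)
                    placed = True
                    break
            if not placed:
                n_discarded += 1
                logger.warning(
                    "unit of %d block(s) on %s unplaceable on %d tracks; discarded",
                    len(unit),
                    chrom,
                    S,
                )
        for k in range(S):
            if not chrom_tracks[k]:
                logger.warning("chromosome %s: track %d is empty", chrom, k + 1)
        tracks[chrom] = chrom_tracks
        provenance[chrom] = chrom_prov
        n_genes[chrom] = ref.n_genes(chrom)

    if n_discarded:
        logger.warning("%d unplaceable unit(s) discarded in total", n_discarded)
    if not tracks:
        raise ValueError("no reference chromosome has collinear blocks")
    assignment = SubgenomeAssignment(
        S=S, n_genes=n_genes, tracks=tracks, provenance=provenance
    )
    return label_dominance(assignment)


def label_dominance(assignment: SubgenomeAssignment) -> SubgenomeAssignment:
    """Order tracks by total retained genes, most-retained (dominant) first.

    Exact ties keep the input track order, making the arbitrary assignment
    of equally fractionated tracks deterministic.
    """
    counts = assignment.retained_counts()
    # stable sort on negative counts keeps input order on ties
    assignment.dominance_order = [int(k) for k in np.argsort(-counts, kind="stable")]
    return assignment
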