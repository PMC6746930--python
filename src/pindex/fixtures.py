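"""End-to-end synthetic test genomes with planted fractionation truth.

The generator builds an intact ancestor genome (standing in for the
outgroup reference), duplicates it into S subgenome copies, deletes genes
from each copy in geometric-length runs, and writes everything to disk in
the same dialects the readers consume: reference gene tables (BED / GFF3 /
TSV), a query gene table, anchor pairs (TSV and MCScanX-style
collinearity) and a truth table. Because the planted subgenome of every
query gene is known, partitioning, dominance labelling, retention
windowing and the index itself can all be validated without any external
data.

Scenarios
---------
balanced          S=2, equal retention (autopolyploid-like null).
biased            S=2, distinct retention targets (allopolyploid-like).
two_round         S=4, two stacked duplications: older round biased
                  between sibling-pair groups, younger round balanced
                  within each group.
decaploid_grouped S=5 with a planted 2+3 group structure (two retention
                  regimes), for the pairwise distance-matrix grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import simulate_losses

__all__ = [
    "FixtureTruth",
    "make_polyploid_fixture",
    "make_event_table_fixture",
    "random_retention_profile",
]

_SCENARIOS = {
    "balanced": dict(S=2, retention=(0.6, 0.6)),
    "biased": dict(S=2, retention=(0.75, 0.40)),
    "two_round": dict(
        S=4, retention=(0.75, 0.75, 0.45, 0.45), pairing=((0, 1), (2, 3))
    ),
    "decaploid_grouped": dict(
        S=5, retention=(0.75, 0.75, 0.45, 0.45, 0.45), grouping=((0, 1), (2, 3, 4))
    ),
}

_BP_PER_GENE = 1000


@dataclass
class FixtureTruth:
    """Planted ground truth of one synthetic polyploid bundle."""

    scenario: str
    seed: int
    S: int
    retention_targets: tuple[float, ...]
    masks: dict[str, np.ndarray]  # ref chrom -> (S, n_genes) retained flags
    subgenome_of_gene: dict[str, int]  # query gene id -> subgenome index
    pairing: tuple | None = None
    grouping: tuple | None = None
    files: dict[str, Path] = field(default_factory=dict)

    def observed_retention(self) -> np.ndarray:
        """Recount per-subgenome retention from the masks."""
        total = sum(m.shape[1] for m in self.masks.values())
        kept = np.sum([m.sum(axis=1) for m in self.masks.values()], axis=0)
        return kept / total


def _write_ref_files(out: Path, masks: dict[str, np.ndarray]) -> dict[str, Path]:
    bed_path, gff_path, tsv_path = out / "ref.bed", out / "ref.gff3", out / "ref.tsv"
    with open(bed_path, "w") as bed, open(gff_path, "w") as gff, open(
        tsv_path, "w"
    ) as tsv:
        gff.write("##gff-version 3\n")
        tsv.write("gene_id\tchromosome\tstart\tend\tstrand\n")
        for chrom in masks:
            n = masks[chrom].shape[1]
            for rank in range(n):
                gid = f"anc{chrom[3:]}g{rank:04d}"
                start1 = rank * _BP_PER_GENE + 1  # 1-based inclusive
                end1 = start1 + _BP_PER_GENE // 2
                bed.write(f"{chrom}\t{start1 - 1}\t{end1}\t{gid}\t0\t+\n")
                gff.write(
                    f"{chrom}\tsynth\tgene\t{start1}\t{end1}\t.\t+\t.\tID={gid}\n"
                )
                tsv.write(f"{gid}\t{chrom}\t{start1}\t{end1}\t+\n")
    return {"ref_bed": bed_path, "ref_gff3": gff_path, "ref_tsv": tsv_path}


def _segment_edges(n: int, n_segments: int, rng) -> list[int]:
    if n_segments <= 1:
        return [0, n]
    cuts = sorted(rng.choice(np.arange(1, n), size=n_segments - 1, replace=False))
    return [0, *map(int, cuts), n]


def make_polyploid_fixture(
    out_dir: str | Path,
    scenario: str = "balanced",
    n_chromosomes: int = 10,
    genes_per_chromosome: int = 2000,
    S: int | None = None,
    retention: tuple[float, ...] | None = None,
    run_length_p: float = 0.5,
    seed: int = 0,
    n_segments: int = 1,
    redistribute: bool = False,
) -> FixtureTruth:
    """Generate a polyploid genome bundle with known subgenome truth.

    ``n_segments > 1`` shatters every (reference chromosome x subgenome)
    copy into that many collinear blocks; ``redistribute=True`` additionally
    scatters the segments of each subgenome onto fresh query chromosomes
    (segments never mix subgenomes). Raises if ``retention`` length differs
    from S.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {list(_SCENARIOS)}")
    preset = _SCENARIOS[scenario]
    S = S if S is not None else preset["S"]
    retention = tuple(retention) if retention is not None else preset["retention"]
    if len(retention) != S:
        raise ValueError(f"{len(retention)} retention values for S={S}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    masks: dict[str, np.ndarray] = {}
    for c in range(n_chromosomes):
        chrom = np.empty((S, genes_per_chromosome), dtype=bool)
        for k in range(S):
            chrom[k] = simulate_losses(
                genes_per_chromosome, retention[k], run_length_p, rng
            )
        masks[f"chr{c + 1}"] = chrom

    files = _write_ref_files(out, masks)

    # query genes: retained copies laid out per subgenome, optionally
    # shattered into segments and redistributed onto new chromosomes
    qry_rows = []  # gene_id, chromosome, start, end, strand
    anchors = []  # ref_gene, qry_gene, block_id, ref_chrom, qry_chrom
    subgenome_of_gene: dict[str, int] = {}
    block_serial = 0
    for chrom, mask in masks.items():
        cnum = chrom[3:]
        n = mask.shape[1]
        for k in range(S):
            edges = _segment_edges(n, n_segments, rng)
            for seg, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                ranks = np.flatnonzero(mask[k, lo:hi]) + lo
                if ranks.size == 0:
                    continue
                if redistribute:
                    qchrom = f"scaf{block_serial + 1}_s{k + 1}"
                    offset = 0
                else:
                    qchrom = f"chr{cnum}_s{k + 1}"
                    offset = lo
                block_id = str(block_serial)
                block_serial += 1
                for pos, rank in enumerate(ranks):
                    gid = f"anc{cnum}g{rank:04d}_s{k + 1}"
                    start1 = (offset + pos) * _BP_PER_GENE + 1
                    qry_rows.append(
                        (gid, qchrom, start1, start1 + _BP_PER_GENE // 2, "+")
                    )
                    subgenome_of_gene[gid] = k
                    anchors.append(
                        (f"anc{cnum}g{rank:04d}", gid, block_id, chrom, qchrom)
                    )

    qry_path = out / "qry.tsv"
    pd.DataFrame(
        qry_rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).to_csv(qry_path, sep="\t", index=False)
    files["qry_tsv"] = qry_path

    anchor_path = out / "anchors.tsv"
    adf = pd.DataFrame(
        anchors, columns=["ref_gene", "qry_gene", "block_id", "ref_chrom", "qry_chrom"]
    )
    adf[["ref_gene", "qry_gene", "block_id"]].to_csv(anchor_path, sep="\t", index=False)
    files["anchors_tsv"] = anchor_path

    coll_path = out / "blocks.collinearity"
    with open(coll_path, "w") as fh:
        fh.write("############### synthetic collinearity ###############\n")
        for block_id, sub in adf.groupby("block_id", sort=False):
            fh.write(
                f"## Alignment {block_id}: score={float(len(sub)):.1f} "
                f"e_value=0 N={len(sub)} "
                f"{sub['ref_chrom'].iloc[0]}&{sub['qry_chrom'].iloc[0]} plus\n"
            )
            for i, row in enumerate(sub.itertuples(index=False)):
                fh.write(f"{block_id}-{i:>3}:\t{row.ref_gene}\t{row.qry_gene}\t0\n")
    files["collinearity"] = coll_path

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# scenario\t{scenario}\n# seed\t{seed}\n# S\t{S}\n")
        fh.write(f"# retention\t{','.join(str(r) for r in retention)}\n")
        if "pairing" in preset:
            fh.write(f"# pairing\t{preset['pairing']}\n")
        if "grouping" in preset:
            fh.write(f"# grouping\t{preset['grouping']}\n")
        fh.write("ref_chrom\tref_rank\tref_gene\tsubgenome\tretained\n")
        for chrom, mask in masks.items():
            cnum = chrom[3:]
            for k in range(S):
                for rank in range(mask.shape[1]):
                    fh.write(
                        f"{chrom}\t{rank}\tanc{cnum}g{rank:04d}\t{k + 1}"
                        f"\t{int(mask[k, rank])}\n"
                    )
    files["truth"] = truth_path

    return FixtureTruth(
        scenario=scenario,
        seed=seed,
        S=S,
        retention_targets=retention,
        masks=masks,
        subgenome_of_gene=subgenome_of_gene,
        pairing=preset.get("pairing"),
        grouping=preset.get("grouping"),
        files=files,
    )


def random_retention_profile(
    rng: np.random.Generator,
    S: int = 2,
    n_chromosomes: tuple[int, int] = (1, 20),
    n_windows: tuple[int, int] = (5, 50),
    M: int = 100,
):
    """A random valid retention profile (uniform rates per window).

    Used for randomized validation suites: retention rates are drawn
    uniformly in [0, 1] per subgenome and window, for a random number of
    chromosomes and windows within the given inclusive ranges.
    """
    from .retention import RetentionProfile

    K = int(rng.integers(n_chromosomes[0], n_chromosomes[1] + 1))
    rates, counts = {}, {}
    for c in range(K):
        N = int(rng.integers(n_windows[0], n_windows[1] + 1))
        rates[f"c{c + 1}"] = rng.random((S, N))
        counts[f"c{c + 1}"] = np.full(N, M, dtype=int)
    return RetentionProfile(rates=rates, window_gene_counts=counts, M=M)


def make_event_table_fixture(path: str | Path) -> Path:
    """Copy the packaged 24-event transcription to ``path``; returns the path."""
    from importlib.resources import files as _files

    path = Path(path)
    source = _files("pindex").joinpath("data/event_table.tsv")
    path.write_text(source.read_text())
    return path
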