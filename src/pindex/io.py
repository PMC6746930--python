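"""Readers and writers for gene tables, collinearity files and results.

All downstream computation is carried out on *gene ranks*: the 0-based
position of a gene in start-coordinate order along its chromosome. Rank
intervals are half-open everywhere. Base-pair coordinates are parsed and
kept, but windows and retention statistics never use them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLocus",
    "GenePositionTable",
    "AnchorPair",
    "CollinearBlock",
    "CollinearBlockSet",
    "EventTableFixture",
    "read_gene_positions",
    "read_collinearity",
    "read_event_fixture",
    "write_result",
    "read_result",
]


@dataclass(frozen=True)
class GeneLocus:
    """One annotated gene: id, chromosome, bp span, strand and rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1


class GenePositionTable:
    """Ordered gene loci of one genome, rank-indexed per chromosome.

    Parameters
    ----------
    records : DataFrame with columns gene_id, chromosome, start, end, strand.
        Ranks are (re)assigned here: 0-based per chromosome in start order,
        ties broken by end then gene_id, so the table is deterministic for
        any input ordering.
    genome_label : free-text name of the genome.
    """

    def __init__(self, records: pd.DataFrame, genome_label: str = ""):
        required = {"gene_id", "chromosome", "start", "end"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        df = records.copy()
        if "strand" not in df.columns:
            df["strand"] = "."
        if df.empty:
            raise ValueError("gene table is empty")
        dup = df["gene_id"].duplicated()
        if dup.any():
            offenders = df.loc[dup, "gene_id"].head(10).tolist()
            raise ValueError(f"duplicate gene ids: {offenders}")
        bad = df["start"] > df["end"]
        if bad.any():
            raise ValueError(
                f"start > end for genes: {df.loc[bad, 'gene_id'].head(10).tolist()}"
            )
        df = df.sort_values(
            ["chromosome", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = df.groupby("chromosome", sort=False).cumcount()
        self.genome_label = genome_label
        self.df = df[["gene_id", "chromosome", "start", "end", "strand", "rank"]]
        self._rank_of = dict(zip(df["gene_id"], df["rank"]))
        self._chrom_of = dict(zip(df["gene_id"], df["chromosome"]))
        self._sizes = df.groupby("chromosome", sort=False).size().to_dict()

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank_of

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sizes)

    def n_genes(self, chromosome: str) -> int:
        return self._sizes[chromosome]

    def rank(self, gene_id: str) -> int:
        return self._rank_of[gene_id]

    def chromosome_of(self, gene_id: str) -> str:
        return self._chrom_of[gene_id]

    def loci(self) -> Iterable[GeneLocus]:
        for row in self.df.itertuples(index=False):
            yield GeneLocus(
                row.gene_id, row.chromosome, row.start, row.end, row.strand, row.rank
            )


@dataclass(frozen=True)
class AnchorPair:
    """A collinear (reference gene, query gene) pair inside a block."""

    ref_gene_id: str
    qry_gene_id: str
    block_id: str


@dataclass
class CollinearBlock:
    """One collinear block: an aligned run of anchor pairs.

    Rank intervals are half-open over gene ranks; orientation is '+' when
    query ranks increase with reference ranks, '-' when they decrease.
    """

    block_id: str
    ref_chromosome: str
    ref_interval: tuple[int, int]
    qry_chromosome: str
    qry_interval: tuple[int, int]
    orientation: str
    anchors: list[AnchorPair]
    score: float = 0.0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class CollinearBlockSet:
    blocks: list[CollinearBlock] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


@dataclass
class EventTableFixture:
    """Transcription of the 24 catalogued paleopolyploidy events.

    Each event carries one row per (checked genome, reference genome)
    combination with the published divergence index, plus the nature label
    printed for the event (Allo, Auto, or unlabeled where the table leaves
    the column blank).
    """

    events: pd.DataFrame  # event_number, event_name, printed_nature,
    #                       checked_genome, reference_genome, pindex_value

    @property
    def n_events(self) -> int:
        return self.events["event_number"].nunique()

    def rows_for(self, event_number: int) -> pd.DataFrame:
        return self.events[self.events["event_number"] == event_number]


# ---------------------------------------------------------------------------
# gene position readers

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF_NAME_RE = re.compile(r"(?:^|;)\s*Name=([^;]+)")


def _parse_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature.lower() != "gene":
                continue
            m = _GFF_ID_RE.search(attrs) or _GFF_NAME_RE.search(attrs)
            if m is None:
                raise ValueError(f"{path}: line {lineno}: gene feature without ID")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            rows.append((m.group(1), chrom, start_i, end_i, strand))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )


def _parse_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs >=4 fields, got {len(parts)}"
                )
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                # BED is 0-based half-open; store 1-based inclusive like GFF
                start_i, end_i = int(start) + 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            rows.append((name, chrom, start_i, end_i, strand))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )


def _parse_gene_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["gene_id", "chromosome", "start", "end", "strand"]
    if list(df.columns[:4]) != expected[:4]:
        # headerless: positional columns
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: str})
        if df.shape[1] < 4:
            raise ValueError(f"{path}: gene TSV needs >=4 columns")
        df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
        df.columns = expected[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "."
    return df[expected]


def read_gene_positions(
    path: str | Path, dialect: str = "tsv", genome_label: str | None = None
) -> GenePositionTable:
    """Read gene loci from ``path`` in the ``gff3``, ``bed`` or ``tsv`` dialect.

    Returns a :class:`GenePositionTable` with per-chromosome 0-based ranks
    assigned by start coordinate (ties: end, then gene_id). Raises
    ``ValueError`` on unparseable lines (named by line number), duplicate
    gene ids, or an empty file.
    """
    path = Path(path)
    parsers = {"gff3": _parse_gff3, "bed": _parse_bed, "tsv": _parse_gene_tsv}
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}; use gff3, bed or tsv")
    df = parsers[dialect](path)
    if df.empty:
        raise ValueError(f"{path}: no gene records parsed")
    label = genome_label if genome_label is not None else path.stem
    return GenePositionTable(df, genome_label=label)


# ---------------------------------------------------------------------------
# collinearity readers

_MCSCANX_HEADER_RE = re.compile(r"^##\s*Alignment:?\s+(\S+?):?\s+(.*)$")


def _iter_mcscanx_anchors(path: Path):
    """Yield (block_id, ref_gene, qry_gene, lineno) from a .collinearity file."""
    block_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _MCSCANX_HEADER_RE.match(line)
            if m is not None:
                block_id = m.group(1)
                continue
            if line.startswith("#"):
                continue
            fields = line.replace(":", " ").split()
            # forms: "<block>-<n>: ref qry [evalue]" or "ref qry [evalue]"
            genes = [f for f in fields if not re.fullmatch(r"[\d\-.eE+]+", f)]
            if len(genes) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: cannot find two gene ids"
                )
            if block_id is None:
                raise ValueError(
                    f"{path}: line {lineno}: anchor before any '## Alignment' header"
                )
            yield block_id, genes[0], genes[1], lineno


def _iter_tsv_anchors(path: Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:3] != ["ref_gene", "qry_gene", "block_id"]:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 3:
            raise ValueError(f"{path}: anchor TSV needs 3 columns")
        df = df.iloc[:, :3]
        df.columns = ["ref_gene", "qry_gene", "block_id"]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        yield str(row.block_id), row.ref_gene, row.qry_gene, i


def read_collinearity(
    path: str | Path,
    dialect: str,
    ref: GenePositionTable,
    qry: GenePositionTable,
) -> CollinearBlockSet:
    """Read collinear anchor pairs and assemble rank-interval blocks.

    ``dialect`` is ``mcscanx`` (``.collinearity`` output) or ``tsv``
    (columns ref_gene, qry_gene, block_id). Every gene id must resolve in
    the reference or query table; orientation is inferred from query-rank
    monotonicity. Blocks with fewer than 2 anchors are kept with a warning.
    """
    path = Path(path)
    if dialect == "mcscanx":
        anchors_iter = _iter_mcscanx_anchors(path)
    elif dialect == "tsv":
        anchors_iter = _iter_tsv_anchors(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use mcscanx or tsv")

    by_block: dict[str, list[AnchorPair]] = {}
    unresolved: list[str] = []
    for block_id, g1, g2, _lineno in anchors_iter:
        # anchors may be written (ref, qry) or (qry, ref); disambiguate
        if g1 in ref and g2 in qry:
            rg, qg = g1, g2
        elif g2 in ref and g1 in qry:
            rg, qg = g2, g1
        else:
            for g in (g1, g2):
                if g not in ref and g not in qry:
                    unresolved.append(g)
            continue
        by_block.setdefault(block_id, []).append(AnchorPair(rg, qg, block_id))
    if unresolved:
        raise ValueError(
            f"{path}: {len(unresolved)} gene ids resolve in neither table; "
            f"first offenders: {unresolved[:10]}"
        )
    if not by_block:
        raise ValueError(f"{path}: no anchor pairs parsed")

    blocks = []
    for block_id, anchors in by_block.items():
        if len(anchors) < 2:
            logger.warning(
                "block %s has %d anchor(s); kept", block_id, len(anchors)
            )
        anchors = sorted(anchors, key=lambda a: ref.rank(a.ref_gene_id))
        ref_chroms = {ref.chromosome_of(a.ref_gene_id) for a in anchors}
        qry_chroms = {qry.chromosome_of(a.qry_gene_id) for a in anchors}
        if len(ref_chroms) > 1 or len(qry_chroms) > 1:
            raise ValueError(
                f"block {block_id} spans multiple chromosomes "
                f"(ref {sorted(ref_chroms)}, qry {sorted(qry_chroms)})"
            )
        rranks = [ref.rank(a.ref_gene_id) for a in anchors]
        qranks = [qry.rank(a.qry_gene_id) for a in anchors]
        orientation = "+"
        if len(qranks) >= 2 and qranks[-1] < qranks[0]:
            orientation = "-"
        blocks.append(
            CollinearBlock(
                block_id=block_id,
                ref_chromosome=ref_chroms.pop(),
                ref_interval=(min(rranks), max(rranks) + 1),
                qry_chromosome=qry_chroms.pop(),
                qry_interval=(min(qranks), max(qranks) + 1),
                orientation=orientation,
                anchors=anchors,
                score=float(len(anchors)),
            )
        )
    blocks.sort(key=lambda b: (b.ref_chromosome, b.ref_interval, b.block_id))
    return CollinearBlockSet(blocks)


# ---------------------------------------------------------------------------
# event-table fixture

_EVENT_COLUMNS = [
    "event_number",
    "event_name",
    "printed_nature",
    "checked_genome",
    "reference_genome",
    "pindex_value",
]


def read_event_fixture(path: str | Path | None = None) -> EventTableFixture:
    """Load the packaged transcription of the 24 published polyploidy events.

    ``path`` overrides the packaged file (same TSV layout). Values are kept
    exactly as printed (two decimals); the nature column is Allo, Auto or
    ``unlabeled`` where the publication leaves it blank.
    """
    if path is None:
        from importlib.resources import files

        path = files("pindex").joinpath("data/event_table.tsv")
        df = pd.read_csv(str(path), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _EVENT_COLUMNS:
        raise ValueError(f"malformed event table: columns {list(df.columns)}")
    if df["pindex_value"].min() < 0 or df["pindex_value"].max() > 1:
        raise ValueError("event table pindex values outside [0, 1]")
    fixture = EventTableFixture(events=df)
    return fixture


# ---------------------------------------------------------------------------
# result writer / reader

def write_result(result, path: str | Path) -> None:
    """Write a fitted result as a key/value header plus per-chromosome TSV.

    The file round-trips losslessly through :func:`read_result` (floats are
    serialized at full precision).
    """
    path = Path(path)
    payload = result.to_dict()
    with open(path, "w") as fh:
        fh.write("# pindex result\n")
        for key in ("mode", "status", "pindex", "S"):
            fh.write(f"{key}\t{payload[key]!r}\n")
        fh.write(f"params\t{json.dumps(payload['params'], sort_keys=True)}\n")
        fh.write("## per_chromosome\n")
        per_chrom = pd.DataFrame(payload["per_chromosome"])
        per_chrom.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_result(path: str | Path) -> dict:
    """Parse a file written by :func:`write_result` back into a dict."""
    path = Path(path)
    header: dict = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "## per_chromosome":
                in_table = True
                continue
            if line.startswith("#"):
                continue
            if in_table:
                table_lines.append(line)
            elif line:
                key, value = line.split("\t", 1)
                if key == "params":
                    header[key] = json.loads(value)
                else:
                    import ast

                    header[key] = ast.literal_eval(value)
    from io import StringIO

    per_chrom = (
        pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
        if len(table_lines) > 1
        else pd.DataFrame()
    )
    header["per_chromosome"] = per_chrom.to_dict(orient="list")
    return header
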