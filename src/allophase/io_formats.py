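"""Readers and writers for every on-disk representation the toolkit touches.

Formats handled here: FASTA (assemblies, proteins, CDS), the 7-column
tab-separated gene-coordinate table, 12-column tabular protein hits,
newick trees, and a flat INI-style configuration file.

Coordinate convention: gene tables are 1-based inclusive on disk and
0-based half-open in memory; the conversion happens exactly once in each
direction, inside :func:`read_gene_table` / :func:`write_gene_table`.
"""

from __future__ import annotations

import configparser
import gzip
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violated a structural invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One gene in the custom coordinate table (in-memory: 0-based half-open)."""

    chromosome: str
    gene_id: str
    start: int
    end: int
    strand: str
    order: int
    original_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class HitRecord:
    """One row of a 12-column tabular protein hit file."""

    query_gene: str
    subject_gene: str
    identity: float
    length: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def score(self) -> float:
        return self.bitscore


@dataclass
class GenomeComplex:
    """Assemblies, gene annotations and sequences for one species.

    ``chromosomes`` maps chromosome id to nucleotide sequence; ``genes`` is
    ordered by (chromosome, order); ``cds`` and ``proteins`` map gene id to
    sequence.  ``ploidy_label`` is a free-text tag such as ``"AABBDD"``.
    """

    species_id: str
    chromosomes: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)
    cds: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    ploidy_label: str = ""

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def gene_orders(self) -> dict[str, tuple[str, int]]:
        """gene id -> (chromosome, order rank)."""
        return {g.gene_id: (g.chromosome, g.order) for g in self.genes}

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def validate(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise ValidationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chromosome}")
            if g.end > len(self.chromosomes[g.chromosome]):
                raise ValidationError(f"gene {g.gene_id} beyond chromosome end")
        _check_dense_orders(self.genes)


def _check_dense_orders(records: list[GeneRecord]) -> None:
    per_chrom: dict[str, list[int]] = {}
    for r in records:
        per_chrom.setdefault(r.chromosome, []).append(r.order)
    offenders = []
    for chrom, orders in per_chrom.items():
        if sorted(orders) != list(range(1, len(orders) + 1)):
            offenders.append(chrom)
    if offenders:
        raise ValidationError(
            "gene order not dense (must be 1..n per chromosome) on: "
            + ", ".join(sorted(offenders)))


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence map.

    The id is the header token before the first whitespace; the description
    is dropped.  Duplicate ids and empty headers are rejected.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ParseError(f"{path}: FASTA record with empty id")
            if name in out:
                raise ParseError(f"{path}: duplicate FASTA id {name!r}")
            out[name] = seq.upper()
    return out


def write_fasta(seqs: dict[str, str], path, wrap_width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            if not name:
                raise ValidationError("cannot write FASTA record with empty id")
            fh.write(f">{name}\n")
            if wrap_width and wrap_width > 0:
                for i in range(0, len(seq), wrap_width):
                    fh.write(seq[i:i + wrap_width] + "\n")
            else:
                fh.write(seq + "\n")


# --------------------------------------------------------------------------
# gene table (7 tab-separated columns)
# --------------------------------------------------------------------------

GENE_TABLE_COLUMNS = (
    "chromosome", "gene_id", "start", "end", "strand", "order", "original_id")


def read_gene_table(path) -> list[GeneRecord]:
    """Read the 7-column gene coordinate table.

    Columns: chromosome, gene_id, start, end, strand, order, original_id —
    exactly seven; extra or missing columns are rejected.  On-disk
    coordinates are 1-based inclusive.
    """
    records: list[GeneRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(parts)}")
            chrom, gid, start, end, strand, order, orig = parts
            try:
                start_i, end_i, order_i = int(start), int(end), int(order)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate/order") from exc
            records.append(GeneRecord(
                chromosome=chrom, gene_id=gid,
                start=start_i - 1, end=end_i,   # disk 1-based incl -> memory 0-based half-open
                strand=strand, order=order_i, original_id=orig))
    records.sort(key=lambda r: (r.chromosome, r.order))
    _check_dense_orders(records)
    return records


def write_gene_table(records: list[GeneRecord], path) -> None:
    records = sorted(records, key=lambda r: (r.chromosome, r.order))
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write("\t".join([
                r.chromosome, r.gene_id,
                str(r.start + 1), str(r.end),   # memory 0-based half-open -> disk 1-based incl
                r.strand, str(r.order), r.original_id or r.gene_id]) + "\n")


# --------------------------------------------------------------------------
# 12-column hits
# --------------------------------------------------------------------------

def read_hits(path) -> list[HitRecord]:
    """Read a 12-column tabular hit file; rows preserved in file order.

    Self-hits are retained — downstream callers filter as needed.
    """
    hits: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                hits.append(HitRecord(
                    query_gene=parts[0], subject_gene=parts[1],
                    identity=float(parts[2]), length=int(parts[3]),
                    mismatches=int(parts[4]), gapopens=int(parts[5]),
                    qstart=int(parts[6]), qend=int(parts[7]),
                    sstart=int(parts[8]), send=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field") from exc
    return hits


def write_hits(hits: list[HitRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_gene, h.subject_gene, h.identity, h.length,
                h.mismatches, h.gapopens, h.qstart, h.qend, h.sstart,
                h.send, h.evalue, h.bitscore)) + "\n")


# --------------------------------------------------------------------------
# newick trees
# --------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ParseError(f"{path}: cannot parse newick tree: {exc}") from exc


def read_tree_string(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ParseError(f"cannot parse newick tree: {exc}") from exc


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# --------------------------------------------------------------------------
# config + logging plumbing
# --------------------------------------------------------------------------

def read_config(path) -> dict[str, dict[str, str]]:
    """Flat key=value sections per pipeline stage (INI dialect)."""
    cp = configparser.ConfigParser()
    with _open_text(path) as fh:
        cp.read_file(fh)
    return {section: dict(cp.items(section)) for section in cp.sections()}


def write_config(config: dict[str, dict[str, str]], path) -> None:
    cp = configparser.ConfigParser()
    for section, kv in config.items():
        cp[section] = {k: str(v) for k, v in kv.items()}
    with _open_text(path, "wt") as fh:
        cp.write(fh)


def get_logger(name: str = "allophase") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(stage: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    log = logger or get_logger()
    t0 = time.perf_counter()
    log.info("stage %s: start", stage)
    try:
        yield
    finally:
        log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
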