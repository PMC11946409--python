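"""Circular genome, gene models and genetic-code helpers.

Mitochondrial genomes of the organisms this package targets are small
(~20 kb) circular molecules densely packed with CDS, tRNA and rRNA genes on
both strands.  All coordinates in this package are 1-based inclusive, and
coordinate arithmetic is modulo the genome length: a gene with ``end <
start`` wraps around the origin of the (arbitrary) linearisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP = "*"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def codon_table(table_id: int) -> CodonTable.CodonTable:
    """NCBI genetic code by numeric id (1 = standard, 4 = mold/protozoan mito)."""
    return CodonTable.unambiguous_dna_by_id[table_id]


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; stop codons yield ``*``.

    Raises ``ValueError`` for codons containing ambiguous bases.
    """
    table = codon_table(table_id)
    if codon in table.stop_codons:
        return STOP
    try:
        return table.forward_table[codon]
    except KeyError:
        raise ValueError(f"cannot translate ambiguous codon {codon!r}")


def is_stop(codon: str, table_id: int = 1) -> bool:
    return codon in codon_table(table_id).stop_codons


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence with 1-based wrap-around coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("genome sequence is empty")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in genome: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def normalize(self, pos: int) -> int:
        """Map any integer coordinate onto [1, length] (modulo arithmetic)."""
        return (pos - 1) % self.length + 1

    def base(self, pos: int) -> str:
        return self.sequence[self.normalize(pos) - 1]

    def fetch(self, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive; ``end < start`` wraps
        around the origin."""
        start = self.normalize(start)
        end = self.normalize(end)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


def read_fasta(path: str | Path) -> CircularGenome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return CircularGenome(id=record.id, sequence=str(record.seq).upper())


def write_fasta(genome: CircularGenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([record], str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """One annotated feature on the circular genome.

    ``start``/``end`` are 1-based inclusive genome coordinates; ``end <
    start`` means the feature wraps around the origin.  ``strand`` is the
    transcript strand.  CDS features must have a span length divisible by 3.
    """

    gene_id: str
    feature_type: str  # CDS | tRNA | rRNA | ORF
    start: int
    end: int
    strand: str
    translation_table: int = 1

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.feature_type not in {"CDS", "tRNA", "rRNA", "ORF"}:
            raise ValueError(f"{self.gene_id}: unknown feature type {self.feature_type!r}")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    @property
    def is_coding(self) -> bool:
        return self.feature_type in {"CDS", "ORF"}

    def span_length(self, genome_length: int) -> int:
        return (self.end - self.start) % genome_length + 1

    def validate(self, genome_length: int) -> None:
        if self.is_coding and self.span_length(genome_length) % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id} span length {self.span_length(genome_length)} "
                "is not divisible by 3"
            )

    def genome_positions(self, genome_length: int) -> Iterator[int]:
        """Genome positions covered, in plus-strand order from ``start``."""
        for i in range(self.span_length(genome_length)):
            yield (self.start - 1 + i) % genome_length + 1

    def contains(self, pos: int, genome_length: int) -> bool:
        return self.offset_of(pos, genome_length) is not None

    def offset_of(self, pos: int, genome_length: int) -> int | None:
        """0-based transcript offset of genome position ``pos`` (strand-aware),
        or None when the position is outside the feature."""
        plus_off = (pos - self.start) % genome_length
        if plus_off >= self.span_length(genome_length):
            return None
        if self.strand == "+":
            return plus_off
        return self.span_length(genome_length) - 1 - plus_off

    def position_at(self, offset: int, genome_length: int) -> int:
        """Genome position of 0-based transcript offset (strand-aware)."""
        n = self.span_length(genome_length)
        if not 0 <= offset < n:
            raise IndexError(f"offset {offset} outside {self.gene_id} (length {n})")
        if self.strand == "+":
            return (self.start - 1 + offset) % genome_length + 1
        return (self.start - 1 + (n - 1 - offset)) % genome_length + 1

    def transcript_seq(self, genome: CircularGenome) -> str:
        """The feature sequence on its transcript strand."""
        seq = genome.fetch(self.start, self.end)
        return revcomp(seq) if self.strand == "-" else seq


def genes_at(models: Sequence[GeneModel], pos: int, genome_length: int,
             coding_only: bool = False) -> list[GeneModel]:
    hits = [m for m in models if m.contains(pos, genome_length)]
    if coding_only:
        hits = [m for m in hits if m.is_coding]
    return hits


# -- GFF3-style I/O ----------------------------------------------------------
#
# The wrap-around convention used here (end < start on the circle, flagged
# with a wraps_origin=true attribute) is deliberately non-standard, so the
# reader/writer are minimal and local.

_GFF_COLUMNS = 9


def write_gff3(models: Sequence[GeneModel], genome: CircularGenome,
               path: str | Path) -> None:
    lines = ["##gff-version 3",
             f"##sequence-region {genome.id} 1 {genome.length}"]
    for m in models:
        attrs = [f"ID={m.gene_id}", f"transl_table={m.translation_table}"]
        if m.wraps_origin:
            attrs.append("wraps_origin=true")
        phase = "0" if m.is_coding else "."
        lines.append("\t".join([
            genome.id, "mitoedit", m.feature_type, str(m.start), str(m.end),
            ".", m.strand, phase, ";".join(attrs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != _GFF_COLUMNS:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
        models.append(GeneModel(
            gene_id=attrs.get("ID", f"feature{len(models) + 1}"),
            feature_type=fields[2],
            start=int(fields[3]),
            end=int(fields[4]),
            strand=fields[6],
            translation_table=int(attrs.get("transl_table", 1)),
        ))
    return models
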