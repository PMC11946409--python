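"""Editing-site detection from matched DNA-seq / RNA-seq pileups.

The caller compares, at every sufficiently covered position, the majority
non-reference RNA allele against the DNA consensus base.  The editing level
is the percentage of RNA reads supporting the edited allele; DNA
heterogeneity (the percentage of DNA reads supporting the majority
non-consensus base) screens out genomic variants masquerading as edits.
Substitution type is interpreted on the transcript strand of the containing
gene: A→G is reported as A-to-I (inosine reads as guanosine in reverse
transcription), C→T as C-to-U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CircularGenome, GeneModel, complement, genes_at
from .pileup import BASES, BASE_INDEX, PileupTable, SiteCounts

logger = logging.getLogger(__name__)

A_TO_I = "A-to-I"
C_TO_U = "C-to-U"
OTHER = "other"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Thresholds:
    """Detection and analysis thresholds.

    All "more than" thresholds are strict: a site qualifies only when the
    value exceeds the threshold.  ``min_rna_depth`` of 11 encodes "more than
    10 filtered reads".
    """

    min_rna_depth: int = 11
    call_level_pct: float = 50.0
    high_level_pct: float = 90.0
    dna_het_max_pct: float = 5.0
    compare_level_pct: float = 10.0
    kaks_apply_level_pct: float = 50.0

    def __post_init__(self) -> None:
        if self.min_rna_depth < 1:
            raise ValueError("min_rna_depth must be >= 1")
        for name in ("call_level_pct", "high_level_pct", "dna_het_max_pct",
                     "compare_level_pct", "kaks_apply_level_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class EditingSite:
    """One candidate editing site (all bases in plus-strand orientation)."""

    position: int
    ref_base: str  # DNA consensus
    alt_base: str  # majority non-reference RNA base
    raw_type: str  # e.g. "A>G(+)"
    transcript_type: str  # A-to-I | C-to-U | other | unassigned
    editing_level: float  # percent
    rna_depth: int
    dna_depth: int
    dna_heterogeneity: float | None  # percent; None when DNA depth is 0
    gene_ids: tuple[str, ...] = ()
    strand: str = "."  # transcript strand used for typing; '.' if unassigned
    excluded_heterogeneous: bool = False


def heterogeneity(site: SiteCounts, ref_base: str,
                  mode: str = "major_nonref") -> float | None:
    """Per-site DNA heterogeneity score in percent.

    Default: 100 × (count of the most frequent non-reference base) / depth.
    ``mode='one_minus_major'`` gives the alternative 100 × (1 − majority
    fraction).  Returns None (missing, never 0) at zero depth.
    """
    depth = site.depth
    if depth == 0:
        return None
    counts = site.as_array()
    if mode == "major_nonref":
        nonref = [counts[i] for i, b in enumerate(BASES) if b != ref_base]
        return 100.0 * max(nonref) / depth
    if mode == "one_minus_major":
        return 100.0 * (1.0 - counts.max() / depth)
    raise ValueError(f"unknown heterogeneity mode {mode!r}")


def editing_level(ref_base: str, rna_site: SiteCounts, alt_base: str) -> float | None:
    """100 × (reads supporting the edited allele) / (total reads at the site).

    Returns None at zero depth.
    """
    if alt_base == ref_base:
        raise ValueError("alt_base must differ from ref_base")
    depth = rna_site.depth
    if depth == 0:
        return None
    return 100.0 * rna_site.count(alt_base) / depth


def classify_substitution(ref_base: str, alt_base: str, strand: str) -> tuple[str, str]:
    """Type a substitution on the transcript strand.

    Returns ``(raw_type, transcript_type)`` where ``raw_type`` keeps the
    plus-strand pair.  A→G on the transcript strand is A-to-I (inosine pairs
    like guanosine), C→T is C-to-U; anything else is ``other``.  With an
    unassigned strand the type is ``unassigned``.
    """
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"invalid nucleotide {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    raw = f"{ref_base}>{alt_base}({strand if strand in '+-' else '.'})"
    if strand not in {"+", "-"}:
        return raw, UNASSIGNED
    r, a = (ref_base, alt_base) if strand == "+" else (
        complement(ref_base), complement(alt_base))
    if (r, a) == ("A", "G"):
        return raw, A_TO_I
    if (r, a) == ("C", "T"):
        return raw, C_TO_U
    return raw, OTHER


def _consensus_base(dna_counts: np.ndarray, fasta_base: str) -> str:
    """Majority DNA base; ties broken toward the FASTA reference base."""
    best = dna_counts.max()
    winners = [BASES[i] for i in range(4) if dna_counts[i] == best]
    if fasta_base in winners:
        return fasta_base
    return winners[0]


def call_sites(dna: PileupTable, rna: PileupTable, genome: CircularGenome,
               gene_models: Sequence[GeneModel],
               thresholds: Thresholds = Thresholds()) -> list[EditingSite]:
    """Call candidate editing sites over the whole genome.

    A site is emitted iff its RNA depth is at least ``min_rna_depth``, DNA
    depth is at least 1, and the majority non-consensus RNA allele has at
    least one supporting read.  Sites whose DNA heterogeneity exceeds
    ``dna_het_max_pct`` are emitted with ``excluded_heterogeneous=True`` and
    are skipped by the summary statistics.  Only the majority non-reference
    RNA allele is evaluated (one edit per site).  Transcript type comes from
    the strand of the containing gene(s); overlapping genes on opposite
    strands leave the site unassigned.  Output is sorted by position.
    """
    if dna.genome_length != genome.length or rna.genome_length != genome.length:
        raise ValueError("pileup length does not match genome length")
    L = genome.length
    ref_idx = np.fromiter((BASE_INDEX.get(b, 0) for b in genome.sequence),
                          dtype=np.int64, count=L)
    rna_depths = rna.depths
    dna_depths = dna.depths

    # vectorised pre-filter: candidate positions with adequate coverage and
    # at least one RNA read off the DNA consensus
    dna_major = dna.counts.argmax(axis=1)
    # ties toward FASTA base handled per candidate below; for the prefilter
    # any non-consensus RNA read suffices
    covered = (rna_depths >= thresholds.min_rna_depth) & (dna_depths >= 1)
    rna_nonmajor = rna_depths - rna.counts[np.arange(L), dna_major]
    rna_nonref = rna_depths - rna.counts[np.arange(L), ref_idx]
    candidates = np.nonzero(covered & ((rna_nonmajor > 0) | (rna_nonref > 0)))[0]

    sites: list[EditingSite] = []
    for i in candidates:
        pos = int(i) + 1
        dna_counts = dna.counts[i]
        ref = _consensus_base(dna_counts, genome.base(pos))
        rna_counts = rna.counts[i]
        # deterministic tie-break: highest count, then alphabetical base
        nonref = [(int(rna_counts[BASE_INDEX[b]]), b) for b in BASES if b != ref]
        best = max(c for c, _ in nonref)
        alt = next(b for c, b in nonref if c == best)
        alt_count = best
        if alt_count == 0:
            continue
        level = 100.0 * alt_count / rna_counts.sum()
        het = heterogeneity(SiteCounts(pos, *map(int, dna_counts)), ref)
        excluded = het is not None and het > thresholds.dna_het_max_pct
        hits = genes_at(gene_models, pos, L)
        strands = {m.strand for m in hits}
        strand = strands.pop() if len(strands) == 1 else "."
        raw, ttype = classify_substitution(ref, alt, strand if strand in "+-" else "unassigned")
        sites.append(EditingSite(
            position=pos, ref_base=ref, alt_base=alt, raw_type=raw,
            transcript_type=ttype, editing_level=level,
            rna_depth=int(rna_counts.sum()), dna_depth=int(dna_counts.sum()),
            dna_heterogeneity=het,
            gene_ids=tuple(m.gene_id for m in hits),
            strand=strand, excluded_heterogeneous=excluded,
        ))
    sites.sort(key=lambda s: s.position)
    return sites


def sites_above(sites: Sequence[EditingSite], level_pct: float,
                include_excluded: bool = False) -> list[EditingSite]:
    """Sites with editing level strictly above ``level_pct`` (heterogeneous
    sites dropped unless requested)."""
    return [s for s in sites
            if s.editing_level > level_pct
            and (include_excluded or not s.excluded_heterogeneous)]


# -- site table I/O ----------------------------------------------------------

_TSV_COLUMNS = ["pos", "ref", "alt", "raw_type", "transcript_type", "level",
                "rna_depth", "dna_depth", "dna_het", "strand", "genes",
                "excluded_heterogeneous"]


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pos": s.position, "ref": s.ref_base, "alt": s.alt_base,
        "raw_type": s.raw_type, "transcript_type": s.transcript_type,
        "level": s.editing_level, "rna_depth": s.rna_depth,
        "dna_depth": s.dna_depth,
        "dna_het": "." if s.dna_heterogeneity is None else s.dna_heterogeneity,
        "strand": s.strand, "genes": ",".join(s.gene_ids) or ".",
        "excluded_heterogeneous": s.excluded_heterogeneous,
    } for s in sites], columns=_TSV_COLUMNS)


def write_sites_tsv(sites: Sequence[EditingSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False,
                                 float_format="%.6f")


def write_sites_vcf(sites: Sequence[EditingSite], genome: CircularGenome,
                    path: str | Path) -> None:
    """VCF-like editing-site table: INFO carries EL (editing level, %), DP
    (RNA depth), HET (DNA heterogeneity, %), TT (transcript type), GENES."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.id},length={genome.length}>",
        '##INFO=<ID=EL,Number=1,Type=Float,Description="RNA editing level (%)">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="RNA read depth">',
        '##INFO=<ID=HET,Number=1,Type=Float,Description="DNA heterogeneity (%)">',
        '##INFO=<ID=TT,Number=1,Type=String,Description="Transcript-strand substitution type">',
        '##INFO=<ID=GENES,Number=.,Type=String,Description="Containing genes">',
        '##FILTER=<ID=het,Description="DNA heterogeneity above threshold">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for s in sites:
        het = "." if s.dna_heterogeneity is None else f"{s.dna_heterogeneity:.4f}"
        info = (f"EL={s.editing_level:.4f};DP={s.rna_depth};HET={het};"
                f"TT={s.transcript_type};GENES={','.join(s.gene_ids) or '.'}")
        filt = "het" if s.excluded_heterogeneous else "PASS"
        lines.append("\t".join([genome.id, str(s.position), ".", s.ref_base,
                                s.alt_base, ".", filt, info]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites_vcf(path: str | Path) -> list[EditingSite]:
    sites: list[EditingSite] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _, ref, alt, _, filt, info = line.split("\t")[:8]
        kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
        genes = tuple(g for g in kv.get("GENES", ".").split(",") if g != ".")
        het = None if kv.get("HET", ".") == "." else float(kv["HET"])
        ttype = kv.get("TT", UNASSIGNED)
        sites.append(EditingSite(
            position=int(pos), ref_base=ref, alt_base=alt,
            raw_type=f"{ref}>{alt}(.)", transcript_type=ttype,
            editing_level=float(kv["EL"]), rna_depth=int(kv["DP"]),
            dna_depth=0, dna_heterogeneity=het, gene_ids=genes,
            strand=".", excluded_heterogeneous=(filt == "het"),
        ))
    return sites
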