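"""Per-site base-count tables (pileups) and their readers.

A :class:`PileupTable` holds, for one sample, the number of aligned read
bases A/C/G/T observed at every position of the circular genome, always
reported on the genome plus strand.  Tables can be built from coordinate
sorted SAM text (via pysam) or read from a plain TSV (``pos A C G T``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import CircularGenome

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_MATCH = {0, 7, 8}  # M, =, X consume both query and reference
_CIGAR_QUERY_ONLY = {1, 4}  # I, S consume query only
_CIGAR_REF_ONLY = {2, 3}  # D, N consume reference only


@dataclass(frozen=True)
class SiteCounts:
    """Base counts at one genome position (plus-strand orientation)."""

    position: int
    A: int
    C: int
    G: int
    T: int

    @property
    def depth(self) -> int:
        return self.A + self.C + self.G + self.T

    def count(self, base: str) -> int:
        return getattr(self, base)

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.C, self.G, self.T], dtype=np.int64)


class PileupTable:
    """Dense per-position A/C/G/T counts over the whole circular genome."""

    def __init__(self, sample_id: str, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if (counts < 0).any():
            raise ValueError("negative base counts")
        self.sample_id = sample_id
        self.counts = counts

    @classmethod
    def zeros(cls, sample_id: str, genome_length: int) -> "PileupTable":
        return cls(sample_id, np.zeros((genome_length, 4), dtype=np.int64))

    @property
    def genome_length(self) -> int:
        return self.counts.shape[0]

    def site(self, pos: int) -> SiteCounts:
        a, c, g, t = self.counts[pos - 1]
        return SiteCounts(position=pos, A=int(a), C=int(c), G=int(g), T=int(t))

    def depth(self, pos: int) -> int:
        return int(self.counts[pos - 1].sum())

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add_base(self, pos: int, base: str, n: int = 1) -> None:
        idx = BASE_INDEX.get(base)
        if idx is not None:  # N and other ambiguity codes are not tallied
            self.counts[(pos - 1) % self.genome_length, idx] += n

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "pos", np.arange(1, self.genome_length + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None,
                 genome_length: int | None = None) -> "PileupTable":
        df = pd.read_csv(path, sep="\t")
        required = {"pos", *BASES}
        if not required.issubset(df.columns):
            raise ValueError(f"pileup TSV must have columns {sorted(required)}")
        length = genome_length if genome_length is not None else int(df["pos"].max())
        counts = np.zeros((length, 4), dtype=np.int64)
        counts[df["pos"].to_numpy() - 1] = df[list(BASES)].to_numpy()
        return cls(sample_id or Path(path).stem, counts)


def pileup_from_sam(path: str | Path, genome: CircularGenome,
                    sample_id: str | None = None) -> PileupTable:
    """Tally aligned read bases from SAM text into a plus-strand pileup.

    Insertions and soft clips contribute nothing; deleted reference
    positions are left untouched; alignments whose span runs past the end
    of the reference are wrapped modulo the genome length (origin-spanning
    reads may also arrive as two-part alignments, which tally naturally).
    Records that fail basic consistency checks are skipped with a warning.
    """
    table = PileupTable.zeros(sample_id or Path(path).stem, genome.length)
    n_skipped = 0
    text = Path(path).read_text().splitlines()
    header_text = "\n".join(l for l in text if l.startswith("@"))
    header = pysam.AlignmentHeader.from_text(header_text + "\n")
    for line in text:
        if not line or line.startswith("@"):
            continue
        try:
            rec = pysam.AlignedSegment.fromstring(line, header)
        except (ValueError, OSError) as exc:
            n_skipped += 1
            logger.warning("skipping unparseable SAM record: %s", exc)
            continue
        if rec.is_unmapped or rec.cigartuples is None or rec.query_sequence is None:
            n_skipped += 1
            continue
        seq = rec.query_sequence
        query_span = sum(length for op, length in rec.cigartuples
                         if op in _CIGAR_MATCH | _CIGAR_QUERY_ONLY)
        if query_span != len(seq) or rec.reference_start < 0:
            n_skipped += 1
            logger.warning("skipping malformed record %s", rec.query_name)
            continue
        qpos = 0
        rpos = rec.reference_start  # 0-based
        for op, length in rec.cigartuples:
            if op in _CIGAR_MATCH:
                for i in range(length):
                    table.add_base(rpos + i + 1, seq[qpos + i])
                qpos += length
                rpos += length
            elif op in _CIGAR_QUERY_ONLY:
                qpos += length
            elif op in _CIGAR_REF_ONLY:
                rpos += length
            # hard clips / padding consume neither
    if n_skipped:
        logger.warning("%d SAM records skipped", n_skipped)
    return table


def read_pileup(path: str | Path, genome: CircularGenome,
                sample_id: str | None = None) -> PileupTable:
    """Build a PileupTable from SAM text or from a ``pos A C G T`` TSV,
    dispatching on the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix == ".sam":
        return pileup_from_sam(path, genome, sample_id)
    return PileupTable.from_tsv(path, sample_id, genome_length=genome.length)
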