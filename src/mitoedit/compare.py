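"""Between-strain comparison of editing repertoires.

Homologous coding sequences of two strains are globally aligned
(Needleman–Wunsch, linear gap penalty) and editing sites are lined up
through the alignment columns: a column counts once either strain edits it
above the comparison threshold, and is *shared* when both strains exceed
the threshold with the same transcript-strand substitution type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection import EditingSite, Thresholds
from .genome import CircularGenome, GeneModel

SHARED = "shared"
UNIQUE_A = "unique_a"
UNIQUE_B = "unique_b"


@dataclass(frozen=True)
class SiteCorrespondence:
    """Aligned-position mapping between two homologous sequences.

    ``pairs`` lists (pos_in_a, pos_in_b) for match/mismatch columns only,
    1-based, strictly increasing in both coordinates.
    """

    gene_pair_id: str
    pairs: tuple[tuple[int, int], ...]
    score: float
    gap_columns: int
    length_a: int
    length_b: int


def align_homologs(cds_a: str, cds_b: str, gene_pair_id: str = "pair",
                   match: float = 1.0, mismatch: float = -1.0,
                   gap: float = -2.0) -> SiteCorrespondence:
    """Global Needleman–Wunsch alignment with a linear gap penalty.

    Traceback ties are broken deterministically: diagonal, then up (gap in
    the second sequence), then left.  Only match/mismatch columns enter the
    correspondence.
    """
    if not cds_a or not cds_b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(cds_a), len(cds_b)
    a = np.frombuffer(cds_a.encode(), dtype=np.uint8)
    b = np.frombuffer(cds_b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match, mismatch)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        best = np.maximum(diag, up)
        # fold in the left-moving chain: H[i,j] = max_{k<=j}(cand[k] + (j-k)*gap)
        cand = np.concatenate(([H[i, 0]], best))
        shifted = cand - gap * np.arange(m + 1)
        H[i, 1:] = (np.maximum.accumulate(shifted) + gap * np.arange(m + 1))[1:]
    # traceback
    pairs: list[tuple[int, int]] = []
    gaps = 0
    i, j = n, m
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0:
            sub = match if cds_a[i - 1] == cds_b[j - 1] else mismatch
            if np.isclose(here, H[i - 1, j - 1] + sub):
                pairs.append((i, j))
                i -= 1
                j -= 1
                continue
        if i > 0 and np.isclose(here, H[i - 1, j] + gap):
            gaps += 1
            i -= 1
            continue
        gaps += 1
        j -= 1
    pairs.reverse()
    return SiteCorrespondence(
        gene_pair_id=gene_pair_id, pairs=tuple(pairs), score=float(H[n, m]),
        gap_columns=gaps, length_a=n, length_b=m,
    )


@dataclass
class ComparisonSummary:
    """Shared vs strain-unique editing sites for one gene pair."""

    gene_pair_id: str
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    table: pd.DataFrame  # col, pos_a, pos_b, level_a, level_b, type_a, type_b, status, unaligned


def compare_sites(sites_a: Mapping[int, tuple[float, str]],
                  sites_b: Mapping[int, tuple[float, str]],
                  correspondence: SiteCorrespondence,
                  thresholds: Thresholds = Thresholds(),
                  require_same_type: bool = True) -> ComparisonSummary:
    """Classify aligned editing sites as shared or strain-unique.

    ``sites_a``/``sites_b`` map transcript-local 1-based positions to
    ``(editing level %, transcript type)``.  A column is considered when
    the level strictly exceeds ``compare_level_pct`` in at least one
    strain; it is shared when both exceed it (with the same type, unless
    relaxed).  Sites falling outside the correspondence (gap columns) are
    counted unique with an ``unaligned`` flag.
    """
    thr = thresholds.compare_level_pct
    a2b = {pa: pb for pa, pb in correspondence.pairs}
    b2a = {pb: pa for pa, pb in correspondence.pairs}
    rows = []
    n_shared = n_ua = n_ub = 0
    for col, (pa, pb) in enumerate(correspondence.pairs, start=1):
        la, ta = sites_a.get(pa, (0.0, "."))
        lb, tb = sites_b.get(pb, (0.0, "."))
        above_a, above_b = la > thr, lb > thr
        if not (above_a or above_b):
            continue
        if above_a and above_b and (not require_same_type or ta == tb):
            status = SHARED
            n_shared += 1
        elif above_a and above_b:
            # both edited but with different substitution types: each strain
            # holds a site the other lacks at this column
            status = f"{UNIQUE_A}+{UNIQUE_B}"
            n_ua += 1
            n_ub += 1
        elif above_a:
            status = UNIQUE_A
            n_ua += 1
        else:
            status = UNIQUE_B
            n_ub += 1
        rows.append({"col": col, "pos_a": pa, "pos_b": pb, "level_a": la,
                     "level_b": lb, "type_a": ta, "type_b": tb,
                     "status": status, "unaligned": False})
    # sites in gap columns (no corresponding position in the other strain)
    for pa, (la, ta) in sorted(sites_a.items()):
        if la > thr and pa not in a2b:
            n_ua += 1
            rows.append({"col": 0, "pos_a": pa, "pos_b": 0, "level_a": la,
                         "level_b": 0.0, "type_a": ta, "type_b": ".",
                         "status": UNIQUE_A, "unaligned": True})
    for pb, (lb, tb) in sorted(sites_b.items()):
        if lb > thr and pb not in b2a:
            n_ub += 1
            rows.append({"col": 0, "pos_a": 0, "pos_b": pb, "level_a": 0.0,
                         "level_b": lb, "type_a": ".", "type_b": tb,
                         "status": UNIQUE_B, "unaligned": True})
    table = pd.DataFrame(rows, columns=["col", "pos_a", "pos_b", "level_a",
                                        "level_b", "type_a", "type_b",
                                        "status", "unaligned"])
    return ComparisonSummary(
        gene_pair_id=correspondence.gene_pair_id, n_shared=n_shared,
        n_unique_a=n_ua, n_unique_b=n_ub, table=table,
    )


def transcript_site_map(sites: Sequence[EditingSite], gene: GeneModel,
                        genome: CircularGenome) -> dict[int, tuple[float, str]]:
    """Project genome-coordinate sites into a gene's transcript coordinates
    for comparison (1-based position → (level, transcript type))."""
    out: dict[int, tuple[float, str]] = {}
    for s in sites:
        if s.excluded_heterogeneous:
            continue
        off = gene.offset_of(s.position, genome.length)
        if off is not None:
            out[off + 1] = (s.editing_level, s.transcript_type)
    return out


def compare_gene_pair(gene_a: GeneModel, genome_a: CircularGenome,
                      sites_a: Sequence[EditingSite],
                      gene_b: GeneModel, genome_b: CircularGenome,
                      sites_b: Sequence[EditingSite],
                      thresholds: Thresholds = Thresholds()) -> ComparisonSummary:
    """Align one homologous gene pair and compare its editing sites."""
    corr = align_homologs(gene_a.transcript_seq(genome_a),
                          gene_b.transcript_seq(genome_b),
                          gene_pair_id=f"{gene_a.gene_id}|{gene_b.gene_id}")
    return compare_sites(transcript_site_map(sites_a, gene_a, genome_a),
                         transcript_site_map(sites_b, gene_b, genome_b),
                         corr, thresholds)


def write_comparison_tsv(summaries: Sequence[ComparisonSummary],
                         path: str | Path) -> None:
    frames = []
    for s in summaries:
        df = s.table.copy()
        df.insert(0, "gene_pair", s.gene_pair_id)
        frames.append(df)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["gene_pair", "col", "pos_a", "pos_b",
                                      "level_a", "level_b", "type_a", "type_b",
                                      "status", "unaligned"]))
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
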