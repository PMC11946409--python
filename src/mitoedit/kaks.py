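"""Nei–Gojobori (NG86) Ka/Ks between unedited and edited coding sequences.

The edited CDS is the genome-encoded CDS with every editing site above the
application threshold substituted (strand-aware).  Synonymous and
nonsynonymous *sites* are counted per codon by enumerating the three
single-base changes at each position (changes to stop codons count as
nonsynonymous); *differences* between codon pairs are averaged over all
orderings of the differing positions, excluding pathways that pass through
a stop codon (with an all-excluded fallback to all pathways).  Proportions
are Jukes–Cantor corrected: d = −(3/4)·ln(1 − (4/3)·p).

NA semantics mirror the tabulated convention of the study system: a gene
with zero substitutions reports Ka = Ks = NA; a gene with substitutions but
no synonymous differences reports a real Ka and Ks = NA (hence Ka/Ks = NA)
— the hallmark of an all-nonsynonymous editing repertoire.

Codon pairs in which either codon is a stop or contains an ambiguous base
are eliminated pairwise; the reported gene length excludes only the
terminal stop codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .detection import EditingSite, Thresholds
from .genome import CircularGenome, GeneModel, STOP, complement, translate_codon

NA = None


@dataclass(frozen=True)
class CdsEdit:
    """An edit in CDS-local transcript coordinates (1-based)."""

    position: int
    ref: str
    alt: str
    level: float


def cds_edits_for_gene(sites: Sequence[EditingSite], gene: GeneModel,
                       genome: CircularGenome) -> list[CdsEdit]:
    """Project genome-coordinate editing sites onto one CDS's transcript."""
    edits = []
    for s in sites:
        off = gene.offset_of(s.position, genome.length)
        if off is None:
            continue
        if gene.strand == "+":
            ref, alt = s.ref_base, s.alt_base
        else:
            ref, alt = complement(s.ref_base), complement(s.alt_base)
        edits.append(CdsEdit(off + 1, ref, alt, s.editing_level))
    return sorted(edits, key=lambda e: e.position)


def apply_edits(cds: str, edits: Sequence[CdsEdit], level_threshold: float) -> str:
    """Substitute every edit with level strictly above the threshold.

    Raises ``ValueError`` naming the position when an edit's reference
    allele does not match the sequence.
    """
    seq = list(cds)
    for e in edits:
        if not 1 <= e.position <= len(seq):
            raise ValueError(f"edit position {e.position} outside CDS")
        if seq[e.position - 1] != e.ref:
            raise ValueError(
                f"edit ref mismatch at CDS position {e.position}: "
                f"sequence has {seq[e.position - 1]}, edit claims {e.ref}"
            )
        if e.level > level_threshold:
            seq[e.position - 1] = e.alt
    return "".join(seq)


def ng_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    Per position, the fraction of the 3 single-base changes that are
    synonymous contributes to the synonymous count; changes to stop codons
    are nonsynonymous.  Returns ``(syn_sites, nonsyn_sites)`` summing to 3.
    """
    if translate_codon(codon, table_id) == STOP:
        raise ValueError(f"stop codon {codon} has no NG site counts")
    aa = translate_codon(codon, table_id)
    syn = 0.0
    for i in range(3):
        n_syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            mut_aa = translate_codon(mut, table_id)
            if mut_aa != STOP and mut_aa == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def _pathway_steps(a: str, b: str, order: tuple[int, ...],
                   table_id: int) -> tuple[float, float, bool]:
    """Walk one mutational pathway a→b; returns (syn, nonsyn, passes_stop)."""
    syn = nonsyn = 0.0
    cur = a
    stop_seen = False
    for i in order:
        nxt = cur[:i] + b[i] + cur[i + 1:]
        aa_cur = translate_codon(cur, table_id)
        aa_nxt = translate_codon(nxt, table_id)
        if aa_cur == aa_nxt and STOP not in (aa_cur, aa_nxt):
            syn += 1
        else:
            nonsyn += 1
        if aa_nxt == STOP:
            stop_seen = True
        cur = nxt
    return syn, nonsyn, stop_seen


def ng_diff_counts(codon_a: str, codon_b: str,
                   table_id: int = 1) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons,
    averaged over mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways (including stops, whose steps count as
    nonsynonymous) are averaged instead.  The counts sum to the number of
    differing positions.
    """
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must have length 3")
    diffs = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    if not diffs:
        return 0.0, 0.0
    results = [_pathway_steps(codon_a, codon_b, order, table_id)
               for order in permutations(diffs)]
    valid = [(s, n) for s, n, stop in results if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    syn = sum(s for s, _ in valid) / len(valid)
    nonsyn = sum(n for _, n in valid) / len(valid)
    return syn, nonsyn


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; NA when p ≥ 3/4 (correction undefined)."""
    if p >= 0.75:
        return NA
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """Per-gene NG Ka/Ks summary (one table row)."""

    gene_id: str
    length_bp: int  # CDS length minus the terminal stop codon
    n_codons_analyzed: int  # codon pairs after pairwise stop/N elimination
    n_subs: int
    syn_subs: int
    nonsyn_subs: int
    S: float  # synonymous sites (averaged over both sequences)
    N: float
    Sd: float
    Nd: float
    Ka: float | None
    Ks: float | None
    ka_ks: float | None


def ng_kaks(cds_a: str, cds_b: str, table_id: int = 1,
            gene_id: str = "gene", length_bp: int | None = None,
            zero_subs_na: bool = True) -> KaKsResult:
    """NG86 Ka/Ks between two same-length coding sequences.

    Both sequences must have their terminal stop codon already removed.
    Codon pairs where either codon is a stop or contains a base outside
    ACGT are dropped pairwise.  With ``zero_subs_na`` (default) a pair with
    zero substitutions reports Ka = Ks = NA; ``False`` reports 0 instead.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences have different lengths")
    if len(cds_a) % 3:
        raise ValueError("sequence length not divisible by 3")
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    nd_int = sd_int = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if translate_codon(ca, table_id) == STOP or translate_codon(cb, table_id) == STOP:
            continue  # pairwise elimination of stop-containing codon pairs
        n_codons += 1
        sa, _ = ng_site_counts(ca, table_id)
        sb, _ = ng_site_counts(cb, table_id)
        S_a += sa
        S_b += sb
        sd, nd = ng_diff_counts(ca, cb, table_id)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    # integer substitution counts: round the pathway-averaged totals
    syn_subs = int(round(Sd))
    nonsyn_subs = int(round(Nd))
    n_subs = syn_subs + nonsyn_subs

    if n_subs == 0 and zero_subs_na:
        ka = ks = NA
    else:
        pn = Nd / N if N > 0 else None
        ps = Sd / S if S > 0 else None
        ka = jukes_cantor(pn) if pn is not None else NA
        if Sd == 0 or ps is None:
            # no synonymous differences: Ks (and Ka/Ks) undefined, unless
            # the strict-zero convention is requested
            ks = 0.0 if (Sd == 0 and S > 0 and not zero_subs_na) else NA
        else:
            ks = jukes_cantor(ps)
    ratio = ka / ks if (ka is not None and ks is not None and ks > 0) else NA
    return KaKsResult(
        gene_id=gene_id,
        length_bp=length_bp if length_bp is not None else len(cds_a),
        n_codons_analyzed=n_codons, n_subs=n_subs,
        syn_subs=syn_subs, nonsyn_subs=nonsyn_subs,
        S=S, N=N, Sd=Sd, Nd=Nd, Ka=ka, Ks=ks, ka_ks=ratio,
    )


def gene_kaks(gene: GeneModel, genome: CircularGenome,
              sites: Sequence[EditingSite],
              thresholds: Thresholds = Thresholds()) -> KaKsResult:
    """Table-row Ka/Ks for one gene: unedited CDS versus the CDS with all
    edits above ``kaks_apply_level_pct`` applied.  The terminal stop codon
    is removed from both sequences and from the reported length."""
    cds = gene.transcript_seq(genome)
    edits = cds_edits_for_gene(sites, gene, genome)
    edited = apply_edits(cds, edits, thresholds.kaks_apply_level_pct)
    # strip the terminal stop codon (reported length excludes it)
    cds_core, edited_core = cds[:-3], edited[:-3]
    return ng_kaks(cds_core, edited_core, table_id=gene.translation_table,
                   gene_id=gene.gene_id, length_bp=len(cds_core))


def kaks_table(genome: CircularGenome, gene_models: Sequence[GeneModel],
               sites: Sequence[EditingSite],
               thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-gene results table (Length / Subs / Syn-Subs / Nonsyn-Subs /
    Ka / Ks / Ka/Ks), genes in genome order."""
    usable = [s for s in sites if not s.excluded_heterogeneous]
    rows = []
    for gene in gene_models:
        if not gene.is_coding:
            continue
        r = gene_kaks(gene, genome, usable, thresholds)
        rows.append({
            "gene": r.gene_id, "length_bp": r.length_bp, "subs": r.n_subs,
            "syn_subs": r.syn_subs, "nonsyn_subs": r.nonsyn_subs,
            "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
            "Ka": "NA" if r.Ka is None else r.Ka,
            "Ks": "NA" if r.Ks is None else r.Ks,
            "Ka/Ks": "NA" if r.ka_ks is None else r.ka_ks,
        })
    return pd.DataFrame(rows, columns=["gene", "length_bp", "subs", "syn_subs",
                                       "nonsyn_subs", "S", "N", "Sd", "Nd",
                                       "Ka", "Ks", "Ka/Ks"])


def write_kaks_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
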