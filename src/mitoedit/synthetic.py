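"""Synthetic circular mitochondrial genomes with planted RNA editing.

This module emulates the statistical structure of an organellar
editing-by-deamination system: a ~20 kb gene-dense circular genome whose
coding regions are fragmented by in-frame premature stop codons at the DNA
level, with a truth table of A→G (A-to-I) and C→T (C-to-U) editing sites on
the transcript strand whose edits restore the open reading frames, and
matched DNA-seq / RNA-seq pileups in which the edited-allele read count at
each site is a binomial draw at the site's true editing level.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    CircularGenome,
    GeneModel,
    codon_table,
    complement,
    revcomp,
    translate_codon,
)
from .pileup import BASES, BASE_INDEX, PileupTable

TRUTH_COLUMNS = ["pos", "ref", "alt", "level", "gene", "effect"]

# Stop codons are restored to tryptophan (TGG) by A→G editing:
#   TAG -> TGG (edit offset 1), TGA -> TGG (offset 2), TAA -> TGG (offsets 1+2)
_STOP_RESTORING_OFFSETS = {"TAG": (1,), "TGA": (2,), "TAA": (1, 2)}

_TRNA_LENGTH = 72


class PlacementError(ValueError):
    """Raised when the requested genes cannot be placed on the genome."""


class EligibilityError(ValueError):
    """Raised when more edit sites are requested than eligible positions exist."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic strain.

    Defaults mirror the study system: a 20 kb circular genome, ~358 editing
    sites (≈1.8% of the genome) split 338:20 between A→G and C→T, truth
    levels concentrated above the 90% level, restorative mode on (premature
    stops in DNA removed by editing) and 1000× sequencing depth.
    """

    seed: int = 0
    genome_length: int = 20_000
    n_cds: int = 10
    n_trna: int = 6
    frac_minus_strand: float = 0.3
    n_edit_sites: int = 358
    level_distribution: str = "high"
    level_params: dict = field(default_factory=dict)
    edit_type_ratio: float = 338 / 358
    dna_coverage: float = 1000.0
    rna_coverage: float = 1000.0
    error_rate: float = 0.0
    restorative_mode: bool = True
    frac_noncoding: float = 0.1
    het_sites: tuple[tuple[int, float], ...] = ()
    translation_table: int = 1
    beta_binomial_rho: float = 0.0  # overdispersion of true levels; off by default
    cds_codon_range: tuple[int, int] = (75, 400)

    def __post_init__(self) -> None:
        for name in ("frac_minus_strand", "edit_type_ratio", "error_rate",
                     "frac_noncoding", "beta_binomial_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0 or self.n_edit_sites < 0:
            raise ValueError("genome_length must be positive, n_edit_sites >= 0")
        for pos, frac in self.het_sites:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"heterogeneity fraction at {pos} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible RNG stream per pipeline stage."""
        return np.random.default_rng([int(self.seed), stream])


def _random_sense_codons(rng: np.random.Generator, n: int, table_id: int) -> list[str]:
    table = codon_table(table_id)
    sense = sorted(set(
        a + b + c for a in BASES for b in BASES for c in BASES
    ) - set(table.stop_codons))
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def _build_cds(rng: np.random.Generator, n_codons: int, config: SimConfig) -> str:
    """One CDS on its transcript strand: ATG, sense codons, terminal stop.

    In restorative mode 1–3 internal codons are replaced by premature stop
    codons (never adjacent to the start or the terminal stop).
    """
    table = codon_table(config.translation_table)
    codons = ["ATG"] + _random_sense_codons(rng, n_codons - 2, config.translation_table)
    if config.restorative_mode:
        n_stops = int(rng.integers(1, 4))
        n_stops = min(n_stops, max(1, n_codons - 4))
        slots = rng.choice(np.arange(2, n_codons - 2), size=n_stops, replace=False)
        stops = [str(s) for s in table.stop_codons]
        for slot in slots:
            codons[int(slot)] = stops[int(rng.integers(0, len(stops)))]
    codons.append("TAA")
    return "".join(codons)


def generate_genome(config: SimConfig) -> tuple[CircularGenome, list[GeneModel]]:
    """Generate the circular genome and its gene models.

    Genes (CDS then tRNA) are placed without overlap around the circle with
    random intergenic gaps; the first CDS is placed across the origin
    whenever the genome is long enough for any gene to wrap.
    """
    rng = config.rng(0)
    length = config.genome_length

    lo, hi = config.cds_codon_range
    cds_codons = rng.integers(lo, hi + 1, size=config.n_cds)
    cds_seqs = [_build_cds(rng, int(n), config) for n in cds_codons]
    gene_lengths = [len(s) for s in cds_seqs] + [_TRNA_LENGTH] * config.n_trna
    total = sum(gene_lengths)
    if total > length:
        raise PlacementError(
            f"genes need {total} bp but the genome is only {length} bp"
        )

    strands = np.where(rng.random(len(gene_lengths)) < config.frac_minus_strand,
                       "-", "+")

    # Random gaps between consecutive genes (and back to the first one).
    slack = length - total
    cuts = np.sort(rng.integers(0, slack + 1, size=len(gene_lengths)))
    gaps = np.diff(np.concatenate([[0], cuts]))

    sequence = list("".join(
        BASES[i] for i in rng.integers(0, 4, size=length)
    ))
    models: list[GeneModel] = []
    # Start the first CDS so that it spans the origin when it can.
    first_len = gene_lengths[0]
    start = length - first_len // 2 if first_len >= 2 else 1
    cursor = start
    for idx, glen in enumerate(gene_lengths):
        gene_start = (cursor - 1) % length + 1
        gene_end = (cursor - 1 + glen - 1) % length + 1
        if idx < config.n_cds:
            gene_id = f"gene{idx + 1:02d}"
            feature = "CDS"
            tseq = cds_seqs[idx]
        else:
            gene_id = f"trn{idx - config.n_cds + 1:02d}"
            feature = "tRNA"
            tseq = "".join(BASES[i] for i in rng.integers(0, 4, size=glen))
        strand = str(strands[idx])
        plus_seq = revcomp(tseq) if strand == "-" else tseq
        for i, b in enumerate(plus_seq):
            sequence[(gene_start - 1 + i) % length] = b
        models.append(GeneModel(
            gene_id=gene_id, feature_type=feature, start=gene_start,
            end=gene_end, strand=strand,
            translation_table=config.translation_table,
        ))
        cursor = cursor + glen + int(gaps[idx])

    genome = CircularGenome(id=f"synthetic_mito_seed{config.seed}",
                            sequence="".join(sequence))
    for m in models:
        m.validate(genome.length)
    return genome, models


# -- level distributions -----------------------------------------------------

def _draw_levels(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """True per-site editing levels in (0, 100], by named preset.

    ``high``      mixture modeled on the observed skew: most sites nearly
                  fully edited, a minority partial, a few below the call
                  threshold (weights 0.85 / 0.12 / 0.03).
    ``two_band``  a fraction ``high_fraction`` in (92, 100], the rest in
                  (55, 88] — every site is callable at the 50% level and the
                  fraction above the 90% level is known by construction.
    ``mixed``     uniform on (5, 100].
    ``uniform``   uniform on (0, 100].
    ``constant``  all sites at ``level``.
    """
    name = config.level_distribution
    p = config.level_params
    if name == "high":
        comp = rng.choice(3, size=n, p=[0.85, 0.12, 0.03])
        levels = np.where(
            comp == 0, rng.uniform(90.0, 100.0, size=n),
            np.where(comp == 1, rng.uniform(50.0, 90.0, size=n),
                     rng.uniform(5.0, 50.0, size=n)))
    elif name == "two_band":
        q = float(p.get("high_fraction", 0.85))
        n_high = int(round(q * n))
        levels = np.concatenate([
            rng.uniform(92.0, 100.0, size=n_high),
            rng.uniform(55.0, 88.0, size=n - n_high),
        ])
        rng.shuffle(levels)
    elif name == "mixed":
        levels = rng.uniform(5.0, 100.0, size=n)
    elif name == "uniform":
        levels = rng.uniform(0.0, 100.0, size=n)
    elif name == "constant":
        levels = np.full(n, float(p.get("level", 95.0)))
    else:
        raise ValueError(f"unknown level distribution {name!r}")
    return np.clip(levels, 1e-9, 100.0)


@dataclass(frozen=True)
class _Candidate:
    pos: int  # genome coordinate, 1-based
    ref: str  # plus-strand base
    alt: str  # plus-strand base
    gene: str
    effect: str
    codon_key: tuple[str, int] | None = None  # (gene, codon index) for coding sites


def _coding_candidates(genome: CircularGenome, model: GeneModel,
                       config: SimConfig) -> tuple[list[_Candidate], list[_Candidate]]:
    """Eligible nonsynonymous edit positions in one CDS, split by transcript
    edit type (A→G pool, C→T pool).

    Eligible means: the transcript base is A or C, the deaminated codon is a
    sense codon different in amino acid, and the codon is neither the start
    codon, a premature stop (those get dedicated restorative edits) nor the
    terminal stop.
    """
    L = genome.length
    tseq = model.transcript_seq(genome)
    table_id = model.translation_table
    a_pool: list[_Candidate] = []
    c_pool: list[_Candidate] = []
    for ci in range(1, len(tseq) // 3 - 1):  # skip start codon and terminal stop
        codon = tseq[3 * ci : 3 * ci + 3]
        if translate_codon(codon, table_id) == "*":
            continue
        for off in range(3):
            base = codon[off]
            if base not in "AC":
                continue
            alt_t = "G" if base == "A" else "T"
            edited = codon[:off] + alt_t + codon[off + 1 :]
            if translate_codon(edited, table_id) in ("*",):
                continue
            if translate_codon(edited, table_id) == translate_codon(codon, table_id):
                continue  # only nonsynonymous designs are planted
            offset = 3 * ci + off
            pos = model.position_at(offset, L)
            if model.strand == "+":
                ref_p, alt_p = base, alt_t
            else:
                ref_p, alt_p = complement(base), complement(alt_t)
            cand = _Candidate(pos, ref_p, alt_p, model.gene_id, "nonsynonymous",
                              codon_key=(model.gene_id, ci))
            (a_pool if base == "A" else c_pool).append(cand)
    return a_pool, c_pool


def _restorative_candidates(genome: CircularGenome, model: GeneModel) -> list[_Candidate]:
    """A→G edits converting every internal premature stop codon to TGG."""
    L = genome.length
    tseq = model.transcript_seq(genome)
    out: list[_Candidate] = []
    for ci in range(1, len(tseq) // 3 - 1):
        codon = tseq[3 * ci : 3 * ci + 3]
        offsets = _STOP_RESTORING_OFFSETS.get(codon)
        if offsets is None:
            continue
        for off in offsets:
            offset = 3 * ci + off
            pos = model.position_at(offset, L)
            if model.strand == "+":
                ref_p, alt_p = "A", "G"
            else:
                ref_p, alt_p = "T", "C"
            out.append(_Candidate(pos, ref_p, alt_p, model.gene_id, "stop_loss",
                                  codon_key=(model.gene_id, ci)))
    return out


def _noncoding_candidates(genome: CircularGenome, models: Sequence[GeneModel]) -> tuple[list[_Candidate], list[_Candidate]]:
    """Eligible edit positions outside CDS (tRNA or intergenic)."""
    L = genome.length
    coding = np.zeros(L, dtype=bool)
    trna_strand: dict[int, tuple[str, str]] = {}
    for m in models:
        for pos in m.genome_positions(L):
            if m.is_coding:
                coding[pos - 1] = True
            else:
                trna_strand[pos] = (m.gene_id, m.strand)
    a_pool: list[_Candidate] = []
    c_pool: list[_Candidate] = []
    for pos in range(1, L + 1):
        if coding[pos - 1]:
            continue
        gene, strand = trna_strand.get(pos, (".", "+"))
        base_t = genome.base(pos) if strand == "+" else complement(genome.base(pos))
        if base_t not in "AC":
            continue
        alt_t = "G" if base_t == "A" else "T"
        if strand == "+":
            ref_p, alt_p = base_t, alt_t
        else:
            ref_p, alt_p = complement(base_t), complement(alt_t)
        cand = _Candidate(pos, ref_p, alt_p, gene, "intergenic" if gene == "." else "structural")
        (a_pool if base_t == "A" else c_pool).append(cand)
    return a_pool, c_pool


def _sample(rng: np.random.Generator, pool: list[_Candidate], k: int,
            what: str, used_codons: set | None = None) -> list[_Candidate]:
    """Draw ``k`` candidates without replacement, at most one per codon.

    Designed coding edits never share a codon: pathway averaging over a
    doubly edited codon could otherwise introduce fractional synonymous
    difference counts, which the all-nonsynonymous design forbids.
    """
    chosen: list[_Candidate] = []
    if used_codons is None:
        used_codons = set()
    for i in rng.permutation(len(pool)):
        if len(chosen) == k:
            break
        cand = pool[i]
        if cand.codon_key is not None and cand.codon_key in used_codons:
            continue
        chosen.append(cand)
        if cand.codon_key is not None:
            used_codons.add(cand.codon_key)
    if len(chosen) < k:
        raise EligibilityError(
            f"requested {k} {what} edit sites but only {len(chosen)} eligible positions"
        )
    return chosen


def plant_edits(genome: CircularGenome, models: Sequence[GeneModel],
                config: SimConfig) -> pd.DataFrame:
    """Design the editing-site truth table.

    Columns: ``pos ref alt level gene effect`` — ``pos`` is a 1-based genome
    coordinate, ``ref``/``alt`` are plus-strand bases (A→G / C→T on the
    transcript strand), ``level`` the true editing level in (0, 100].

    In restorative mode every internal premature stop codon receives the
    A→G edit(s) that convert it to tryptophan (TGG); these are labelled
    ``stop_loss`` and drawn at levels above 90 so restoration is complete at
    the 50% application threshold.  All other coding designs are
    nonsynonymous, mirroring the all-nonsynonymous editing pattern of the
    study system.
    """
    rng = config.rng(1)
    records: list[_Candidate] = []
    if config.restorative_mode:
        for m in models:
            if m.is_coding:
                records.extend(_restorative_candidates(genome, m))
    n_rest = len(records)
    if config.n_edit_sites < n_rest:
        raise EligibilityError(
            f"n_edit_sites={config.n_edit_sites} is below the {n_rest} edits "
            "required to restore all premature stop codons"
        )
    n_free = config.n_edit_sites - n_rest
    n_noncoding = int(round(config.frac_noncoding * n_free))
    n_coding = n_free - n_noncoding

    a_pool: list[_Candidate] = []
    c_pool: list[_Candidate] = []
    used = {c.pos for c in records}
    for m in models:
        if m.is_coding:
            a, c = _coding_candidates(genome, m, config)
            a_pool.extend(x for x in a if x.pos not in used)
            c_pool.extend(x for x in c if x.pos not in used)
    used_codons = {c.codon_key for c in records if c.codon_key is not None}
    n_ag = int(round(config.edit_type_ratio * n_coding))
    records.extend(_sample(rng, a_pool, n_ag, "coding A-to-G", used_codons))
    records.extend(_sample(rng, c_pool, n_coding - n_ag, "coding C-to-T", used_codons))

    if n_noncoding:
        a_nc, c_nc = _noncoding_candidates(genome, models)
        n_ag_nc = int(round(config.edit_type_ratio * n_noncoding))
        records.extend(_sample(rng, a_nc, n_ag_nc, "noncoding A-to-G"))
        records.extend(_sample(rng, c_nc, n_noncoding - n_ag_nc, "noncoding C-to-T"))

    # one edit per position (restorative + sampling already avoid clashes,
    # but noncoding/coding pools are disjoint by construction)
    positions = [c.pos for c in records]
    assert len(positions) == len(set(positions))

    levels = _draw_levels(rng, len(records), config)
    # stop-restoring edits are drawn near-complete
    for i, c in enumerate(records):
        if c.effect == "stop_loss":
            levels[i] = rng.uniform(90.0, 100.0)

    truth = pd.DataFrame({
        "pos": positions,
        "ref": [c.ref for c in records],
        "alt": [c.alt for c in records],
        "level": levels,
        "gene": [c.gene for c in records],
        "effect": [c.effect for c in records],
    }).sort_values("pos", kind="mergesort").reset_index(drop=True)
    validate_truth(genome, truth)
    return truth


def validate_truth(genome: CircularGenome, truth: pd.DataFrame) -> None:
    if truth["pos"].duplicated().any():
        raise ValueError("duplicate truth positions")
    for pos, ref in zip(truth["pos"], truth["ref"]):
        if genome.base(int(pos)) != ref:
            raise ValueError(f"truth ref mismatch at {pos}")
    if not ((truth["level"] > 0) & (truth["level"] <= 100)).all():
        raise ValueError("truth levels must lie in (0, 100]")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- pileup simulation -------------------------------------------------------

def _apply_errors(rng: np.random.Generator, counts: np.ndarray,
                  error_rate: float) -> np.ndarray:
    """Per-base substitution error: each read base is replaced, with
    probability ``error_rate``, by one of the other 3 bases uniformly."""
    if error_rate == 0.0:
        return counts
    out = counts.copy()
    L = counts.shape[0]
    for b in range(4):
        n_err = rng.binomial(counts[:, b], error_rate)
        out[:, b] -= n_err
        others = [o for o in range(4) if o != b]
        split = rng.multinomial(n_err, [1 / 3] * 3)
        for k, o in enumerate(others):
            out[:, o] += split[:, k]
    return out


def simulate_pileups(genome: CircularGenome, truth: pd.DataFrame,
                     config: SimConfig) -> tuple[PileupTable, PileupTable]:
    """Simulate matched DNA-seq and RNA-seq base-count tables.

    Depth is Poisson per site; DNA reads are reference except for sequencing
    error and configured heterogeneity sites; RNA edited-allele reads at a
    truth site are Binomial(depth, level/100) — or beta-binomial when
    ``beta_binomial_rho`` > 0 — with error applied on top.  Counts are
    reported on the genome plus strand and always sum to the drawn depth.
    """
    rng = config.rng(2)
    L = genome.length
    ref_idx = np.fromiter((BASE_INDEX[b] for b in genome.sequence),
                          dtype=np.int64, count=L)

    # DNA sample
    dna_depth = rng.poisson(config.dna_coverage, size=L)
    dna = np.zeros((L, 4), dtype=np.int64)
    dna[np.arange(L), ref_idx] = dna_depth
    for pos, frac in config.het_sites:
        i = (pos - 1) % L
        minor = rng.binomial(dna[i, ref_idx[i]], frac)
        alt_choices = [b for b in range(4) if b != ref_idx[i]]
        alt = alt_choices[int(rng.integers(0, 3))]
        dna[i, ref_idx[i]] -= minor
        dna[i, alt] += minor
    dna = _apply_errors(rng, dna, config.error_rate)

    # RNA sample
    rna_depth = rng.poisson(config.rna_coverage, size=L)
    rna = np.zeros((L, 4), dtype=np.int64)
    rna[np.arange(L), ref_idx] = rna_depth
    if len(truth):
        pos_idx = truth["pos"].to_numpy(dtype=np.int64) - 1
        alt_idx = np.array([BASE_INDEX[b] for b in truth["alt"]], dtype=np.int64)
        p = truth["level"].to_numpy(dtype=float) / 100.0
        if config.beta_binomial_rho > 0:
            rho = config.beta_binomial_rho
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            p = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
        n_alt = rng.binomial(rna_depth[pos_idx], p)
        rna[pos_idx, ref_idx[pos_idx]] -= n_alt
        rna[pos_idx, alt_idx] += n_alt
    rna = _apply_errors(rng, rna, config.error_rate)

    return (PileupTable("dna", dna), PileupTable("rna", rna))


# -- optional SAM emission ---------------------------------------------------

def simulate_reads(genome: CircularGenome, truth: pd.DataFrame,
                   config: SimConfig, n_reads: int, read_length: int = 100,
                   sample_id: str = "rna") -> tuple[list[str], PileupTable]:
    """Emit ungapped, perfectly placed reads as SAM record lines, together
    with the pileup the generator itself tallies from those same reads.

    Reads start uniformly on the circle; a read running past the origin is
    split into a two-part alignment (soft-clipped halves sharing a QNAME).
    At a truth site a read shows the edited allele with probability
    level/100; sequencing error is applied per base.  Feeding the SAM back
    through the pileup reader must reproduce the returned table exactly.
    """
    rng = config.rng(3)
    L = genome.length
    truth_at = {int(p): (r, a, lv / 100.0) for p, r, a, lv in
                zip(truth["pos"], truth["ref"], truth["alt"], truth["level"])}
    table = PileupTable.zeros(sample_id, L)
    records: list[str] = []
    other = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}
    for ri in range(n_reads):
        start = int(rng.integers(1, L + 1))
        bases = []
        for i in range(read_length):
            pos = (start - 1 + i) % L + 1
            b = genome.base(pos)
            hit = truth_at.get(pos)
            if hit is not None and rng.random() < hit[2]:
                b = hit[1]
            if config.error_rate > 0 and rng.random() < config.error_rate:
                b = other[b][int(rng.integers(0, 3))]
            bases.append(b)
            table.add_base(pos, b)
        seq = "".join(bases)
        qname = f"read{ri:06d}"
        n1 = min(read_length, L - start + 1)
        if n1 == read_length:
            records.append(_sam_line(qname, 0, genome.id, start,
                                     f"{read_length}M", seq))
        else:
            n2 = read_length - n1
            records.append(_sam_line(qname, 0, genome.id, start,
                                     f"{n1}M{n2}S", seq))
            records.append(_sam_line(qname, 2048, genome.id, 1,
                                     f"{n1}S{n2}M", seq))
    return records, table


def _sam_line(qname: str, flag: int, rname: str, pos: int, cigar: str,
              seq: str) -> str:
    return "\t".join([qname, str(flag), rname, str(pos), "60", cigar,
                      "*", "0", "0", seq, "*"])


def write_sam(records: Sequence[str], genome: CircularGenome,
              path: str | Path) -> None:
    header = ["@HD\tVN:1.6\tSO:unsorted",
              f"@SQ\tSN:{genome.id}\tLN:{genome.length}"]
    Path(path).write_text("\n".join([*header, *records]) + "\n")
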