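"""Codon-level consequences of editing sites and repertoire summaries.

Maps called editing sites into the codons of their containing CDS (one
record per CDS frame — overlapping genes can classify the same site
differently), detects restoration of genome-encoded premature stop codons,
scores amino-acid physicochemical property changes, and aggregates the
editing repertoire (level histogram, codon-position composition, high-level
fraction, per-gene density, genome-wide edited fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import EditingSite, Thresholds, sites_above
from .genome import (
    CircularGenome,
    GeneModel,
    STOP,
    codon_table,
    complement,
    translate_codon,
)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_LOSS = "stop_loss"
STOP_GAIN = "stop_gain"
START_LOSS = "start_loss"

# 5-class physicochemical scheme
AA_CLASSES = {
    "hydrophobic": set("AVLIMFWY"),
    "polar": set("STNQC"),
    "positive": set("KRH"),
    "negative": set("DE"),
    "special": set("GP"),
}
_CLASS_OF = {aa: cls for cls, aas in AA_CLASSES.items() for aa in aas}

PROP_NONE = "none"
PROP_WITHIN = "within_class"
PROP_CHANGE = "class_change"


@dataclass(frozen=True)
class EditEffect:
    """Effect of one editing site in one CDS frame."""

    position: int  # genome coordinate
    gene_id: str
    codon_index: int  # 1-based from CDS start
    codon_position: int  # 1, 2 or 3
    ref_codon: str  # transcript strand
    edited_codon: str
    ref_aa: str
    edited_aa: str
    effect: str
    property_change_class: str
    editing_level: float


def property_change(ref_aa: str, edited_aa: str) -> str:
    """Classify an amino-acid replacement by the 5-class scheme
    (hydrophobic / polar / positive / negative / special); any stop
    involvement counts as a class change."""
    for aa in (ref_aa, edited_aa):
        if aa != STOP and aa not in _CLASS_OF:
            raise ValueError(f"invalid amino acid symbol {aa!r}")
    if ref_aa == edited_aa:
        return PROP_NONE
    if STOP in (ref_aa, edited_aa):
        return PROP_CHANGE
    return PROP_WITHIN if _CLASS_OF[ref_aa] == _CLASS_OF[edited_aa] else PROP_CHANGE


def _classify(ref_codon: str, edited_codon: str, codon_index: int,
              table_id: int) -> tuple[str, str, str]:
    ref_aa = translate_codon(ref_codon, table_id)
    edited_aa = translate_codon(edited_codon, table_id)
    if ref_aa == STOP:
        # any edit inside a genome-encoded stop codon participates in its
        # restoration (TAA needs two A-to-I edits; each is stop_loss)
        effect = STOP_LOSS
    elif edited_aa == STOP and ref_aa != STOP:
        effect = STOP_GAIN
    elif (codon_index == 1
          and ref_codon in codon_table(table_id).start_codons
          and edited_codon not in codon_table(table_id).start_codons):
        effect = START_LOSS
    elif ref_aa == edited_aa:
        effect = SYNONYMOUS
    else:
        effect = NONSYNONYMOUS
    return ref_aa, edited_aa, effect


def annotate_effect(site: EditingSite, gene_models: Sequence[GeneModel],
                    genome: CircularGenome) -> list[EditEffect]:
    """One EditEffect per CDS frame containing the site.

    The codon is extracted on the gene's transcript strand, wrap-aware; the
    edited codon substitutes the site's alt allele at the codon position.
    Sites outside every CDS return an empty list.
    """
    L = genome.length
    out: list[EditEffect] = []
    for model in gene_models:
        if not model.is_coding:
            continue
        offset = model.offset_of(site.position, L)
        if offset is None:
            continue
        codon_index = offset // 3 + 1
        codon_pos = offset % 3 + 1
        codon_start = (codon_index - 1) * 3
        ref_codon = "".join(
            genome.base(model.position_at(codon_start + k, L)) for k in range(3)
        ) if model.strand == "+" else "".join(
            complement(genome.base(model.position_at(codon_start + k, L)))
            for k in range(3)
        )
        # site alleles are plus-strand; flip onto the transcript strand
        t_ref = site.ref_base if model.strand == "+" else complement(site.ref_base)
        t_alt = site.alt_base if model.strand == "+" else complement(site.alt_base)
        edited_codon = (ref_codon[: codon_pos - 1] + t_alt + ref_codon[codon_pos:])
        ref_aa, edited_aa, effect = _classify(
            ref_codon, edited_codon, codon_index, model.translation_table)
        out.append(EditEffect(
            position=site.position, gene_id=model.gene_id,
            codon_index=codon_index, codon_position=codon_pos,
            ref_codon=ref_codon, edited_codon=edited_codon,
            ref_aa=ref_aa, edited_aa=edited_aa, effect=effect,
            property_change_class=property_change(ref_aa, edited_aa),
            editing_level=site.editing_level,
        ))
    return out


def annotate_all(sites: Sequence[EditingSite], gene_models: Sequence[GeneModel],
                 genome: CircularGenome) -> list[EditEffect]:
    effects: list[EditEffect] = []
    for s in sites:
        effects.extend(annotate_effect(s, gene_models, genome))
    return effects


@dataclass(frozen=True)
class StopRestorationReport:
    """Per-gene account of internal DNA-encoded stop codons and whether
    above-threshold edits convert each of them to a sense codon."""

    gene_id: str
    internal_stops: tuple[tuple[int, str], ...]  # (codon_index, codon)
    unrestored: tuple[tuple[int, str], ...]
    restored: bool


def detect_stop_restoration(gene: GeneModel, genome: CircularGenome,
                            effects: Sequence[EditEffect]) -> StopRestorationReport:
    """Check whether editing removes every internal stop codon of ``gene``.

    ``effects`` must already be restricted to the editing levels at which
    edits are considered applied (e.g. level > 50%).  All covering edits of
    a stop codon are applied jointly, so double-edited TAA→TGG counts as
    restored.
    """
    L = genome.length
    tseq = gene.transcript_seq(genome)
    table_id = gene.translation_table
    by_codon: dict[int, list[EditEffect]] = {}
    for e in effects:
        if e.gene_id == gene.gene_id:
            by_codon.setdefault(e.codon_index, []).append(e)
    internal, unrestored = [], []
    n_codons = len(tseq) // 3
    for ci in range(2, n_codons):  # internal codons: exclude start and terminal
        codon = tseq[3 * (ci - 1): 3 * ci]
        if translate_codon(codon, table_id) != STOP:
            continue
        internal.append((ci, codon))
        edited = list(codon)
        for e in by_codon.get(ci, []):
            edited[e.codon_position - 1] = e.edited_codon[e.codon_position - 1]
        if translate_codon("".join(edited), table_id) == STOP:
            unrestored.append((ci, codon))
    return StopRestorationReport(
        gene_id=gene.gene_id, internal_stops=tuple(internal),
        unrestored=tuple(unrestored), restored=not unrestored,
    )


# -- repertoire summary ------------------------------------------------------

LEVEL_BINS = [(lo, lo + 10) for lo in range(0, 100, 10)]  # (0,10] ... (90,100]


@dataclass
class EditingSummary:
    """Aggregate description of one strain's editing repertoire."""

    sample_id: str
    n_sites: int  # candidate sites (level > 0, not heterogeneous)
    n_called: int  # sites above the call-level threshold
    type_counts: dict[str, int]  # among called sites
    level_histogram: dict[str, int]  # 10-wide bins over all candidate sites
    codon_position_counts: dict[int, int]  # among called coding sites
    high_level_fraction_pct: float | None  # coding called sites above 90%
    per_gene_counts: dict[str, int]
    per_gene_density: dict[str, float]  # called sites per bp of gene
    edited_fraction_pct: float  # 100 * called sites / genome length

    def to_json(self, path: str | Path) -> None:
        data = {
            "sample_id": self.sample_id,
            "n_sites": self.n_sites,
            "n_called": self.n_called,
            "type_counts": self.type_counts,
            "level_histogram": self.level_histogram,
            "codon_position_counts": {str(k): v for k, v in
                                      self.codon_position_counts.items()},
            "high_level_fraction_pct": self.high_level_fraction_pct,
            "per_gene_counts": self.per_gene_counts,
            "per_gene_density": self.per_gene_density,
            "edited_fraction_pct": self.edited_fraction_pct,
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def summarize(sites: Sequence[EditingSite], effects: Sequence[EditEffect],
              genome: CircularGenome, gene_models: Sequence[GeneModel],
              thresholds: Thresholds = Thresholds(),
              sample_id: str = "sample") -> EditingSummary:
    """Build the repertoire summary.

    The level histogram uses fixed 10-wide bins (0,10] … (90,100] over all
    candidate sites; codon-position composition and type counts are
    restricted to sites above the call-level threshold; the high-level
    fraction is the share of called coding-region sites edited above the
    high-level threshold; the edited fraction is called sites per genome
    length.  Heterogeneity-excluded sites never contribute.
    """
    usable = [s for s in sites if not s.excluded_heterogeneous]
    called = sites_above(usable, thresholds.call_level_pct)

    hist = {f"({lo},{hi}]": 0 for lo, hi in LEVEL_BINS}
    for s in usable:
        idx = min(int(np.ceil(s.editing_level / 10.0)) - 1, 9)
        idx = max(idx, 0)
        lo, hi = LEVEL_BINS[idx]
        hist[f"({lo},{hi}]"] += 1

    type_counts: dict[str, int] = {}
    for s in called:
        type_counts[s.transcript_type] = type_counts.get(s.transcript_type, 0) + 1

    coding_ids = {m.gene_id for m in gene_models if m.is_coding}
    called_positions = {s.position for s in called}
    effect_positions = {}
    for e in effects:
        if e.position in called_positions and e.gene_id in coding_ids:
            effect_positions.setdefault(e.position, []).append(e)
    codon_pos_counts = {1: 0, 2: 0, 3: 0}
    for recs in effect_positions.values():
        for e in recs:
            codon_pos_counts[e.codon_position] += 1

    coding_models = [m for m in gene_models if m.is_coding]
    coding_called = [s for s in called
                     if any(m.contains(s.position, genome.length)
                            for m in coding_models)]
    if coding_called:
        n_high = sum(1 for s in coding_called
                     if s.editing_level > thresholds.high_level_pct)
        high_frac = 100.0 * n_high / len(coding_called)
    else:
        high_frac = None

    per_gene_counts: dict[str, int] = {m.gene_id: 0 for m in gene_models}
    for s in called:
        for g in s.gene_ids:
            per_gene_counts[g] = per_gene_counts.get(g, 0) + 1
    per_gene_density = {
        m.gene_id: per_gene_counts[m.gene_id] / m.span_length(genome.length)
        for m in gene_models
    }

    return EditingSummary(
        sample_id=sample_id,
        n_sites=len(usable),
        n_called=len(called),
        type_counts=type_counts,
        level_histogram=hist,
        codon_position_counts=codon_pos_counts,
        high_level_fraction_pct=high_frac,
        per_gene_counts=per_gene_counts,
        per_gene_density=per_gene_density,
        edited_fraction_pct=100.0 * len(called) / genome.length,
    )


# -- I/O ---------------------------------------------------------------------

_EFFECT_COLUMNS = ["pos", "gene", "codon_index", "codon_pos", "ref_codon",
                   "edited_codon", "ref_aa", "edited_aa", "effect",
                   "property_change", "level"]


def effects_to_frame(effects: Sequence[EditEffect]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pos": e.position, "gene": e.gene_id, "codon_index": e.codon_index,
        "codon_pos": e.codon_position, "ref_codon": e.ref_codon,
        "edited_codon": e.edited_codon, "ref_aa": e.ref_aa,
        "edited_aa": e.edited_aa, "effect": e.effect,
        "property_change": e.property_change_class, "level": e.editing_level,
    } for e in effects], columns=_EFFECT_COLUMNS)


def write_effects_tsv(effects: Sequence[EditEffect], path: str | Path) -> None:
    effects_to_frame(effects).to_csv(path, sep="\t", index=False,
                                     float_format="%.6f")


def gene_level_matrix(sites: Sequence[EditingSite],
                      gene_models: Sequence[GeneModel],
                      genome: CircularGenome) -> pd.DataFrame:
    """Per-gene editing-level matrix (heatmap analog): one row per edited
    transcript position of each gene with its editing level."""
    rows = []
    for m in gene_models:
        for s in sites:
            off = m.offset_of(s.position, genome.length)
            if off is not None:
                rows.append({"gene": m.gene_id, "transcript_pos": off + 1,
                             "genome_pos": s.position,
                             "level": s.editing_level})
    return pd.DataFrame(rows, columns=["gene", "transcript_pos", "genome_pos",
                                       "level"])
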