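"""Pipeline orchestration: simulate → call → annotate → Ka/Ks → compare.

A :class:`RunConfig` names either real inputs (genome FASTA, GFF3 gene
models, DNA/RNA pileup TSVs) or a :class:`~mitoedit.synthetic.SimConfig`;
``run_pipeline`` executes the stages in order, writes machine-readable
outputs into the run directory, and records a manifest (thresholds, seed,
input digests, per-stage counters).  Reruns of the same config are
byte-identical: the manifest carries no timestamps and every stage is
seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .compare import ComparisonSummary, compare_gene_pair, write_comparison_tsv
from .detection import (
    Thresholds,
    call_sites,
    read_sites_vcf,
    sites_above,
    write_sites_tsv,
    write_sites_vcf,
)
from .effects import (
    annotate_all,
    detect_stop_restoration,
    summarize,
    write_effects_tsv,
)
from .genome import CircularGenome, GeneModel, read_fasta, read_gff3, write_fasta, write_gff3
from .kaks import kaks_table, write_kaks_tsv
from .pileup import PileupTable, read_pileup
from .synthetic import (
    SimConfig,
    generate_genome,
    plant_edits,
    simulate_pileups,
    write_truth,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One pipeline run: exactly one of (real inputs, synthetic config)."""

    out_dir: Path
    genome_path: Path | None = None
    gff_path: Path | None = None
    dna_pileup_path: Path | None = None
    rna_pileup_path: Path | None = None
    sim: SimConfig | None = None
    strain_b_drop_fraction: float | None = None  # synthetic second strain
    thresholds: Thresholds = field(default_factory=Thresholds)
    translation_table: int = 1
    seed: int = 0

    def validate(self) -> None:
        real = [self.genome_path, self.gff_path, self.dna_pileup_path,
                self.rna_pileup_path]
        has_real = any(p is not None for p in real)
        if has_real and self.sim is not None:
            raise ConfigError("provide either real inputs or a synthetic "
                              "config, not both")
        if has_real and not all(p is not None for p in real):
            raise ConfigError("real-input mode needs genome, gff, dna-pileup "
                              "and rna-pileup paths")
        if not has_real and self.sim is None:
            raise ConfigError("no inputs: provide real input paths or a "
                              "synthetic config")
        if self.strain_b_drop_fraction is not None:
            if self.sim is None:
                raise ConfigError("strain_b_drop_fraction requires synthetic mode")
            if not 0.0 <= self.strain_b_drop_fraction <= 1.0:
                raise ConfigError("strain_b_drop_fraction must be in [0, 1]")


_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_THR_KEYS = {f.name for f in dataclasses.fields(Thresholds)}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a plain key=value run config.

    Keys: ``out_dir``, ``seed``, ``genome``/``gff``/``dna_pileup``/
    ``rna_pileup`` (real mode), ``sim.<field>`` (synthetic mode),
    ``thresholds.<field>``, ``strain_b_drop_fraction``,
    ``translation_table``.  Lines starting with ``#`` are comments.
    """
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        kv[key.strip()] = value.strip()

    sim_kv = {k[4:]: v for k, v in kv.items() if k.startswith("sim.")}
    thr_kv = {k[11:]: v for k, v in kv.items() if k.startswith("thresholds.")}

    def convert(value: str, typ):
        if typ is bool:
            return value.lower() in {"1", "true", "yes"}
        return typ(value)

    sim = None
    if sim_kv:
        bad = set(sim_kv) - _SIM_KEYS
        if bad:
            raise ConfigError(f"unknown sim keys: {sorted(bad)}")
        types = {f.name: f.type for f in dataclasses.fields(SimConfig)}
        typed = {}
        for k, v in sim_kv.items():
            t = {"int": int, "float": float, "bool": bool, "str": str}.get(
                str(types[k]).split("|")[0].strip(), str)
            typed[k] = convert(v, t)
        if "seed" not in typed and "seed" in kv:
            typed["seed"] = int(kv["seed"])
        sim = SimConfig(**typed)

    thr_typed = {}
    for k, v in thr_kv.items():
        if k not in _THR_KEYS:
            raise ConfigError(f"unknown threshold key: {k}")
        thr_typed[k] = int(v) if k == "min_rna_depth" else float(v)

    def maybe_path(key: str) -> Path | None:
        return Path(kv[key]) if key in kv else None

    cfg = RunConfig(
        out_dir=Path(kv.get("out_dir", "mitoedit_run")),
        genome_path=maybe_path("genome"),
        gff_path=maybe_path("gff"),
        dna_pileup_path=maybe_path("dna_pileup"),
        rna_pileup_path=maybe_path("rna_pileup"),
        sim=sim,
        strain_b_drop_fraction=(float(kv["strain_b_drop_fraction"])
                                if "strain_b_drop_fraction" in kv else None),
        thresholds=Thresholds(**thr_typed),
        translation_table=int(kv.get("translation_table", 1)),
        seed=int(kv.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StrainData:
    name: str
    genome: CircularGenome
    models: list[GeneModel]
    truth: pd.DataFrame | None
    dna: PileupTable
    rna: PileupTable


def _simulate_strain(sim: SimConfig, name: str) -> StrainData:
    genome, models = generate_genome(sim)
    truth = plant_edits(genome, models, sim)
    dna, rna = simulate_pileups(genome, truth, sim)
    return StrainData(name=name, genome=genome, models=models, truth=truth,
                      dna=dna, rna=rna)


def derive_second_strain(strain_a: StrainData, sim: SimConfig,
                         drop_fraction: float) -> StrainData:
    """A second strain on the same genome whose truth is the first strain's
    with a random fraction of sites dropped (independent read sampling)."""
    sim_b = dataclasses.replace(sim, seed=sim.seed + 1)
    rng = sim_b.rng(9)
    keep = rng.random(len(strain_a.truth)) >= drop_fraction
    truth_b = strain_a.truth[keep].reset_index(drop=True)
    dna, rna = simulate_pileups(strain_a.genome, truth_b, sim_b)
    return StrainData(name=strain_a.name + "_derived", genome=strain_a.genome,
                      models=strain_a.models, truth=truth_b, dna=dna, rna=rna)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "tool": "mitoedit",
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(thr),
        "stages": [],
        "inputs": {},
        "counters": {},
    }

    # -- stage: inputs -------------------------------------------------------
    try:
        if config.sim is not None:
            strain_a = _simulate_strain(config.sim, "strainA")
            write_fasta(strain_a.genome, out / "genome.fasta")
            write_gff3(strain_a.models, strain_a.genome, out / "models.gff3")
            write_truth(strain_a.truth, out / "truth_a.tsv")
            strain_a.dna.to_tsv(out / "dna_pileup_a.tsv")
            strain_a.rna.to_tsv(out / "rna_pileup_a.tsv")
            manifest["inputs"]["sim"] = dataclasses.asdict(config.sim)
            strain_b = None
            if config.strain_b_drop_fraction is not None:
                strain_b = derive_second_strain(
                    strain_a, config.sim, config.strain_b_drop_fraction)
                strain_b.name = "strainB"
                write_truth(strain_b.truth, out / "truth_b.tsv")
                strain_b.dna.to_tsv(out / "dna_pileup_b.tsv")
                strain_b.rna.to_tsv(out / "rna_pileup_b.tsv")
        else:
            genome = read_fasta(config.genome_path)
            models = read_gff3(config.gff_path)
            for m in models:
                m.validate(genome.length)
            strain_a = StrainData(
                name="sample", genome=genome, models=models, truth=None,
                dna=read_pileup(config.dna_pileup_path, genome, "dna"),
                rna=read_pileup(config.rna_pileup_path, genome, "rna"),
            )
            strain_b = None
            for key in ("genome_path", "gff_path", "dna_pileup_path",
                        "rna_pileup_path"):
                p = getattr(config, key)
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        manifest["stages"].append("inputs")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("inputs", exc) from exc

    results: dict = {}
    strains = [s for s in (strain_a, strain_b) if s is not None]
    for strain in strains:
        suffix = "_a" if strain is strain_a else "_b"
        try:
            sites = call_sites(strain.dna, strain.rna, strain.genome,
                               strain.models, thr)
            write_sites_vcf(sites, strain.genome, out / f"edits{suffix}.vcf")
            write_sites_tsv(sites, out / f"edits{suffix}.tsv")
            manifest["counters"][f"n_candidate_sites{suffix}"] = len(sites)
            manifest["counters"][f"n_called_sites{suffix}"] = len(
                sites_above(sites, thr.call_level_pct))
        except Exception as exc:  # noqa: BLE001
            raise StageError("call", exc) from exc
        try:
            called = sites_above(sites, thr.call_level_pct)
            effects = annotate_all(called, strain.models, strain.genome)
            write_effects_tsv(effects, out / f"effects{suffix}.tsv")
            applied = sites_above(sites, thr.kaks_apply_level_pct)
            applied_effects = annotate_all(applied, strain.models, strain.genome)
            restoration = [detect_stop_restoration(g, strain.genome,
                                                   applied_effects)
                           for g in strain.models if g.is_coding]
            pd.DataFrame([{
                "gene": r.gene_id,
                "n_internal_stops": len(r.internal_stops),
                "n_unrestored": len(r.unrestored),
                "restored": r.restored,
            } for r in restoration]).to_csv(
                out / f"restoration{suffix}.tsv", sep="\t", index=False)
            summary = summarize(sites, effects, strain.genome, strain.models,
                                thr, sample_id=strain.name)
            summary.to_json(out / f"summary{suffix}.json")
            results[f"summary{suffix}"] = summary
            results[f"sites{suffix}"] = sites
            results[f"restoration{suffix}"] = restoration
        except Exception as exc:  # noqa: BLE001
            raise StageError("annotate", exc) from exc
        try:
            table = kaks_table(strain.genome, strain.models, sites, thr)
            write_kaks_tsv(table, out / f"kaks{suffix}.tsv")
            results[f"kaks{suffix}"] = table
        except Exception as exc:  # noqa: BLE001
            raise StageError("kaks", exc) from exc
    manifest["stages"] += ["call", "annotate", "kaks"]

    if strain_b is not None:
        try:
            comparisons = []
            models_b = {m.gene_id: m for m in strain_b.models}
            for gene_a in strain_a.models:
                if not gene_a.is_coding or gene_a.gene_id not in models_b:
                    continue
                comparisons.append(compare_gene_pair(
                    gene_a, strain_a.genome, results["sites_a"],
                    models_b[gene_a.gene_id], strain_b.genome,
                    results["sites_b"], thr))
            write_comparison_tsv(comparisons, out / "compare.tsv")
            results["comparisons"] = comparisons
            manifest["counters"]["n_shared"] = sum(c.n_shared for c in comparisons)
            manifest["counters"]["n_unique_a"] = sum(c.n_unique_a for c in comparisons)
            manifest["counters"]["n_unique_b"] = sum(c.n_unique_b for c in comparisons)
            manifest["stages"].append("compare")
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
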