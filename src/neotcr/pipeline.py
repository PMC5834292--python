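"""End-to-end orchestration: simulate -> call -> neoepitopes -> repertoire.

A single :class:`RunConfig` (YAML or dict) drives the four stages in order
and produces a deterministic run manifest recording the configuration hash,
package version and per-stage record counts. Identical config and seed give
byte-identical outputs; the manifest deliberately contains no absolute
paths or timestamps so that two runs of the same configuration can be
compared file-for-file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml
from Bio import SeqIO

from . import __version__
from .somatic import CallingParams, call_cohort, sites_from_pileup_tsvs, write_vcf
from .neoepitope import (
    HlaAnchorProfile,
    apply_missense,
    builtin_pwm,
    candidates_to_rows,
    parse_affinity_table,
    prediction_map,
    screen_mutations,
    CANDIDATE_COLUMNS,
)
from .repertoire import (
    AlignParams,
    aggregate_clonotypes,
    analyze_fastq,
    read_germline,
    repertoire_summary,
    write_clonotype_table,
    write_germline,
    write_summary,
)
from . import simulate as sim


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Completed outputs remain."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    outdir: str
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "call": True, "neoepitopes": True, "repertoire": True,
        }
    )
    calling: CallingParams = field(default_factory=CallingParams)
    hla_allele: str = "HLA-A*24:02"
    discovery_ic50_nm: float = 500.0
    priming_ic50_nm: float = 50.0
    anchor_positions: tuple[int, ...] = (2, 9)
    use_toy_pwm: bool = True
    affinity_table: str | None = None
    dominance_threshold: float = 0.5
    align: AlignParams = field(default_factory=AlignParams)
    # synthetic-input conditions (used when the simulate stage is enabled)
    n_sites: int = 200
    n_variants: int = 20
    true_vaf: float = 0.20
    pileup_error_rate: float = 0.01
    depth_mean: float = 100.0
    n_proteins: int = 5
    n_missense: int = 5
    n_reads: int = 2000
    read_error_rate: float = 0.005
    mixture: tuple[float, ...] = (0.7, 0.2, 0.1)
    # explicit input paths (used when simulate is disabled)
    tumor_pileup: str | None = None
    normal_pileup: str | None = None
    cds_fasta: str | None = None
    mutation_table: str | None = None
    reads_fastq: str | None = None
    germline_fasta: str | None = None
    germline_anchors: str | None = None

    def __post_init__(self) -> None:
        if self.discovery_ic50_nm <= 0 or self.priming_ic50_nm <= 0:
            raise ValueError("affinity thresholds must be positive")
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must lie in (0, 1]")
        unknown = set(self.stages) - {"simulate", "call", "neoepitopes", "repertoire"}
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "calling" in raw and isinstance(raw["calling"], dict):
            raw["calling"] = CallingParams(**raw["calling"])
        if "align" in raw and isinstance(raw["align"], dict):
            raw["align"] = AlignParams(**raw["align"])
        for key in ("anchor_positions", "mixture"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """SHA-256 of the configuration, excluding the output directory."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of earlier stages are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "thresholds": {
            "calling": dataclasses.asdict(config.calling),
            "discovery_ic50_nm": config.discovery_ic50_nm,
            "priming_ic50_nm": config.priming_ic50_nm,
            "anchor_positions": list(config.anchor_positions),
            "dominance_threshold": config.dominance_threshold,
        },
        "stages": {},
    }

    paths = {
        "tumor_pileup": config.tumor_pileup,
        "normal_pileup": config.normal_pileup,
        "cds_fasta": config.cds_fasta,
        "mutation_table": config.mutation_table,
        "reads_fastq": config.reads_fastq,
        "germline_fasta": config.germline_fasta,
        "germline_anchors": config.germline_anchors,
    }

    if config.stages.get("simulate"):
        try:
            counts = _stage_simulate(config, out, paths)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
        manifest["stages"]["simulate"] = counts
        _log("simulate", f"wrote synthetic inputs: {counts}")

    if config.stages.get("call"):
        try:
            counts = _stage_call(config, out, paths)
        except Exception as exc:
            raise PipelineError(f"stage 'call' failed: {exc}") from exc
        manifest["stages"]["call"] = counts
        _log("call", f"{counts['n_calls']} PASS calls from {counts['n_sites']} sites")

    if config.stages.get("neoepitopes"):
        try:
            counts = _stage_neoepitopes(config, out, paths)
        except Exception as exc:
            raise PipelineError(f"stage 'neoepitopes' failed: {exc}") from exc
        manifest["stages"]["neoepitopes"] = counts
        _log("neoepitopes", f"{counts['n_candidates']} candidates from {counts['n_missense']} missense mutations")

    if config.stages.get("repertoire"):
        try:
            counts = _stage_repertoire(config, out, paths)
        except Exception as exc:
            raise PipelineError(f"stage 'repertoire' failed: {exc}") from exc
        manifest["stages"]["repertoire"] = counts
        _log("repertoire", f"{counts['n_clonotypes']} clonotypes from {counts['n_assigned']} assigned reads")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_simulate(config: RunConfig, out: Path, paths: dict) -> dict:
    indir = out / "inputs"
    indir.mkdir(exist_ok=True)

    pspec = sim.PileupSimSpec(
        seed=config.seed,
        n_sites=config.n_sites,
        n_variants=config.n_variants,
        true_vaf=config.true_vaf,
        tumor_depth_mean=config.depth_mean,
        normal_depth_mean=config.depth_mean,
        error_rate=config.pileup_error_rate,
    )
    sites, truth = sim.simulate_pileups(pspec)
    sim.write_pileup_tsv(sites, "tumor", indir / "tumor.tsv")
    sim.write_pileup_tsv(sites, "normal", indir / "normal.tsv")
    truth.to_csv(indir / "pileup_truth.tsv", sep="\t", index=False)
    paths["tumor_pileup"] = str(indir / "tumor.tsv")
    paths["normal_pileup"] = str(indir / "normal.tsv")

    records, mutations = sim.simulate_mutated_proteome(
        n_proteins=config.n_proteins,
        n_missense=config.n_missense,
        seed=config.seed + 1,
    )
    sim.write_fasta(records, indir / "cds.fasta")
    sim.write_mutation_table(mutations, indir / "mutations.tsv")
    paths["cds_fasta"] = str(indir / "cds.fasta")
    paths["mutation_table"] = str(indir / "mutations.tsv")

    germline = sim.builtin_germline()
    write_germline(germline, indir / "germline.fasta", indir / "germline_anchors.tsv")
    rspec = sim.RepertoireSimSpec(
        seed=config.seed + 2,
        n_reads=config.n_reads,
        error_rate=config.read_error_rate,
        frequencies=tuple(config.mixture),
        clones=tuple(sim.default_clone_pairs()[: len(config.mixture)]),
    )
    reads, rtruth = sim.simulate_repertoire_reads(rspec, germline)
    sim.write_fastq(reads, indir / "reads.fastq")
    rtruth.to_csv(indir / "repertoire_truth.tsv", sep="\t", index=False)
    paths["reads_fastq"] = str(indir / "reads.fastq")
    paths["germline_fasta"] = str(indir / "germline.fasta")
    paths["germline_anchors"] = str(indir / "germline_anchors.tsv")

    return {
        "n_sites": len(sites),
        "n_planted_variants": len(truth),
        "n_proteins": len(records),
        "n_mutations": len(mutations),
        "n_reads": len(reads),
    }


def _stage_call(config: RunConfig, out: Path, paths: dict) -> dict:
    if not paths["tumor_pileup"] or not paths["normal_pileup"]:
        raise FileNotFoundError("tumor and normal pileup TSVs are required")
    sites = sites_from_pileup_tsvs(paths["tumor_pileup"], paths["normal_pileup"])
    calls = call_cohort(sites, config.calling)
    write_vcf(calls, out / "calls.vcf", config.calling)
    return {"n_sites": len(sites), "n_calls": len(calls)}


def _stage_neoepitopes(config: RunConfig, out: Path, paths: dict) -> dict:
    if not paths["cds_fasta"] or not paths["mutation_table"]:
        raise FileNotFoundError("CDS FASTA and mutation table are required")
    predictions = None
    pwm = None
    if config.affinity_table:
        predictions = prediction_map(parse_affinity_table(config.affinity_table))
    elif config.use_toy_pwm:
        pwm = builtin_pwm(config.hla_allele)
    else:
        raise FileNotFoundError(
            "no affinity table configured and the toy predictor is disabled"
        )

    cds_by_gene = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(paths["cds_fasta"], "fasta")
    }
    table = sim.read_mutation_table(paths["mutation_table"])
    missense = []
    n_other = 0
    for row in table.itertuples(index=False):
        if row.gene not in cds_by_gene:
            raise ValueError(f"mutation table references unknown gene {row.gene}")
        _, result = apply_missense(
            cds_by_gene[row.gene], int(row.cds_pos), row.alt,
            gene=row.gene, mutant_rna_reads=int(row.mutant_rna_reads),
        )
        if isinstance(result, str):
            n_other += 1
        else:
            missense.append(result)

    anchors = HlaAnchorProfile(config.hla_allele, frozenset(config.anchor_positions))
    candidates = screen_mutations(
        missense, config.hla_allele, predictions=predictions, pwm=pwm, anchors=anchors,
    )
    rows = candidates_to_rows(candidates)
    with (out / "candidates.tsv").open("w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in CANDIDATE_COLUMNS) + "\n")
    with (out / "peptides.fasta").open("w") as fh:
        for i, r in enumerate(rows, start=1):
            fh.write(f">{r['label']}|{i}\n{r['mut_peptide']}\n")
    return {
        "n_mutations": len(table),
        "n_missense": len(missense),
        "n_non_missense": n_other,
        "n_candidates": len(rows),
        "n_priming": sum(1 for r in rows if r["tier"] == "priming"),
        "n_high_risk": sum(1 for r in rows if r["risk"] == "high"),
    }


def _stage_repertoire(config: RunConfig, out: Path, paths: dict) -> dict:
    for key in ("reads_fastq", "germline_fasta", "germline_anchors"):
        if not paths[key]:
            raise FileNotFoundError(f"{key} is required")
    reference = read_germline(paths["germline_fasta"], paths["germline_anchors"])
    assignments = analyze_fastq(paths["reads_fastq"], reference, config.align)
    clonotypes = aggregate_clonotypes(assignments)
    write_clonotype_table(clonotypes, out / "clonotypes.tsv")
    summary = repertoire_summary(clonotypes, config.dominance_threshold)
    write_summary(summary, out / "repertoire_summary.json")
    return {
        "n_assigned": len(assignments),
        "n_clonotypes": sum(len(v) for v in clonotypes.values()),
        "dominant": bool(summary.get("dominant_pair", {}).get("dominant", False)),
    }
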